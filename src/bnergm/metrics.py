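"""Descriptive network metrics standard in the neuroimaging literature:
clustering coefficient C, characteristic path length L, local efficiency
Eloc, global efficiency Eglob, and mean nodal degree K.

L averages shortest-path lengths over reachable pairs only (the convention
of the small-world literature); the number of unreachable pairs is reported
alongside rather than folded into the average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import InvalidInputError, Network, geodesic_distances

__all__ = ["MetricReport", "MetricSummary", "descriptive_metrics", "summarize_simulations"]

METRIC_NAMES = ("clustering_coefficient", "characteristic_path_length",
                "local_efficiency", "global_efficiency", "mean_degree")


@dataclass(frozen=True)
class MetricReport:
    clustering_coefficient: float
    characteristic_path_length: float
    local_efficiency: float
    global_efficiency: float
    mean_degree: float
    n_unreachable_pairs: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in METRIC_NAMES])


@dataclass(frozen=True)
class MetricSummary:
    """Mean and standard error of each metric over a set of networks."""

    mean: MetricReport
    se: MetricReport
    n_networks: int


def _global_efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    inv = np.zeros(len(iu[0]))
    finite = np.isfinite(dist[iu]) & (dist[iu] > 0)
    inv[finite] = 1.0 / dist[iu][finite]
    return float(inv.mean())


def descriptive_metrics(net: Network) -> MetricReport:
    """Compute the five Table-style metrics for one network."""
    n = net.n_nodes
    if n < 2:
        raise InvalidInputError("metrics require at least 2 nodes")
    a = net.adjacency(dtype=np.int64)
    deg = a.sum(axis=0)

    # clustering: triangles through v over C(deg v, 2); 0 when deg < 2
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    local_c = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    c = float(local_c.mean())

    dist = geodesic_distances(net)
    iu = np.triu_indices(n, k=1)
    dv = dist[iu]
    finite = np.isfinite(dv)
    lpath = float(dv[finite].mean()) if finite.any() else float("nan")
    eglob = _global_efficiency(dist)

    # local efficiency: global efficiency of each node's neighbour subgraph
    eloc_terms = []
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        if len(nbrs) < 2:
            eloc_terms.append(0.0)
            continue
        sub = Network.from_adjacency(a[np.ix_(nbrs, nbrs)])
        eloc_terms.append(_global_efficiency(geodesic_distances(sub)))
    eloc = float(np.mean(eloc_terms))

    return MetricReport(
        clustering_coefficient=c,
        characteristic_path_length=lpath,
        local_efficiency=eloc,
        global_efficiency=eglob,
        mean_degree=float(2.0 * net.n_edges / n),
        n_unreachable_pairs=int(np.sum(~finite)),
    )


def summarize_simulations(nets: Sequence[Network]) -> MetricSummary:
    """Sample mean and standard error of each metric over simulated networks."""
    if len(nets) < 2:
        raise InvalidInputError("need at least 2 networks to summarize")
    rows = np.array([descriptive_metrics(net).as_array() for net in nets])
    mean = rows.mean(axis=0)
    se = rows.std(axis=0, ddof=1) / np.sqrt(len(nets))
    return MetricSummary(
        mean=MetricReport(*mean.tolist()),
        se=MetricReport(*se.tolist()),
        n_networks=len(nets),
    )
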