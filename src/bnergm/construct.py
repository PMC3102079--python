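"""Binary network construction from a correlation matrix.

Functional connectivity studies compare networks across subjects by fixing
the relation between node count n and mean degree K at n = K^s, i.e.
K = n^(1/s) -- a relation motivated by the path length of a random network.
The threshold is therefore an edge-count target, not a correlation cutoff:
the E = round(n*K/2) strongest off-diagonal entries become edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import InvalidInputError, Network

__all__ = ["CorrelationMatrix", "threshold_by_s", "DEFAULT_S"]

DEFAULT_S = 2.5  # reproduces mean degree ~6 at n = 90


@dataclass(frozen=True)
class CorrelationMatrix:
    """Square symmetric matrix of pairwise (partial) correlations."""

    values: np.ndarray
    labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("correlation matrix must be square")
        if v.shape[0] < 2:
            raise InvalidInputError("correlation matrix must be at least 2x2")
        if not np.allclose(v, v.T, atol=1e-8):
            raise InvalidInputError("correlation matrix must be symmetric (tol 1e-8)")
        if np.nanmax(np.abs(v)) > 1 + 1e-8:
            raise InvalidInputError("correlation entries must lie in [-1, 1]")
        if self.labels is not None and len(self.labels) != v.shape[0]:
            raise InvalidInputError("label count does not match matrix dimension")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def target_edge_count(n: int, s: float) -> int:
    """E = round(n * K / 2) with K = n^(1/s)."""
    k = n ** (1.0 / s)
    return int(round(n * k / 2.0))


def threshold_by_s(
    corr: CorrelationMatrix, s: float = DEFAULT_S, *, absolute: bool = False
) -> Network:
    """Threshold a correlation matrix to a size-matched binary network.

    The E largest off-diagonal entries (by signed correlation by default,
    absolute value with ``absolute=True``; ties broken by (row, col) order)
    become the edges, so every subject's network has the same mean degree
    K = n^(1/s).
    """
    if s <= 1:
        raise InvalidInputError("s must exceed 1")
    n = corr.n
    if n < 3:
        raise InvalidInputError("need at least 3 nodes")
    e_target = target_edge_count(n, s)
    n_dyads = n * (n - 1) // 2
    if e_target > n_dyads:
        raise InvalidInputError(
            f"target edge count {e_target} exceeds the {n_dyads} available dyads"
        )
    iu = np.triu_indices(n, k=1)
    vals = corr.values[iu]
    if absolute:
        vals = np.abs(vals)
    # stable sort descending by value, ties by (row, col) index order
    order = np.argsort(-vals, kind="stable")[:e_target]
    edges = list(zip(iu[0][order].tolist(), iu[1][order].tolist()))
    return Network(n, edges)
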