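"""ERGM sufficient statistics and their change statistics.

Implements the explanatory network metrics used for whole-brain ERGMs:
edge count, two-path count, geometrically weighted degree (GWD),
geometrically weighted edgewise / non-edgewise / dyadwise shared partner
statistics (GWESP / GWNSP / GWDSP), and the nodematch count of edges joining
nodes with equal categorical attribute.

Geometric weighting follows the Hunter (2007) / statnet convention

    gw(dist; tau) = e^tau * sum_{i>=1} [1 - (1 - e^{-tau})^i] * dist_i,

applied to the ESP, NSP, DSP or degree count vector. The decay parameter
``tau`` is treated as fixed and known.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import InvalidInputError, Network, NodeAttributes, degree_distribution

__all__ = [
    "GW_KINDS",
    "TERM_KINDS",
    "ModelTerm",
    "ModelSpec",
    "SharedPartnerDistributions",
    "shared_partner_distributions",
    "sum_esp_nsp",
    "gw_statistic",
    "count_edges",
    "count_two_paths",
    "count_nodematch",
    "statistic_vector",
    "change_statistics",
]

GW_KINDS = ("gwd", "gwesp", "gwnsp", "gwdsp")
TERM_KINDS = ("edges", "two_path", "gwd", "gwesp", "gwnsp", "gwdsp", "nodematch")

# integer codes shared with the numba engine
TERM_CODES = {k: c for c, k in enumerate(TERM_KINDS)}


@dataclass(frozen=True)
class ModelTerm:
    """One entry of the statistic vector g(y).

    ``tau`` is required for (and only for) geometrically weighted kinds;
    ``attribute`` names the node attribute for (and only for) nodematch.
    """

    kind: str
    tau: Optional[float] = None
    attribute: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in TERM_KINDS:
            raise InvalidInputError(f"unknown term kind {self.kind!r}")
        if self.kind in GW_KINDS:
            if self.tau is None:
                raise InvalidInputError(f"{self.kind} requires a decay parameter tau")
            if self.tau < 0:
                raise InvalidInputError("tau must be nonnegative")
        elif self.tau is not None:
            raise InvalidInputError(f"{self.kind} does not take tau")
        if (self.attribute is not None) != (self.kind == "nodematch"):
            raise InvalidInputError("attribute is given iff kind is nodematch")

    @property
    def name(self) -> str:
        if self.kind in GW_KINDS:
            return f"{self.kind}({self.tau:g})"
        if self.kind == "nodematch":
            return f"nodematch({self.attribute})"
        return self.kind


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of model terms defining the statistic vector g(y)."""

    terms: tuple[ModelTerm, ...]

    def __post_init__(self) -> None:
        terms = tuple(self.terms)
        if len(terms) < 1:
            raise InvalidInputError("a model needs at least one term")
        keys = [(t.kind, t.attribute) for t in terms]
        if len(set(keys)) != len(keys):
            raise InvalidInputError("duplicate (kind, attribute) term")
        object.__setattr__(self, "terms", terms)

    @classmethod
    def of(cls, *kinds: str, tau: float = 0.75, attribute: Optional[str] = None) -> "ModelSpec":
        """Convenience constructor: ``ModelSpec.of("edges", "gwesp")``."""
        terms = []
        for k in kinds:
            if k in GW_KINDS:
                terms.append(ModelTerm(k, tau=tau))
            elif k == "nodematch":
                terms.append(ModelTerm(k, attribute=attribute))
            else:
                terms.append(ModelTerm(k))
        return cls(tuple(terms))

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.terms)

    def needs_attributes(self) -> bool:
        return any(t.kind == "nodematch" for t in self.terms)


@dataclass(frozen=True)
class SharedPartnerDistributions:
    """ESP / NSP / DSP count vectors indexed by shared-partner count 0..n-2."""

    esp: np.ndarray
    nsp: np.ndarray
    dsp: np.ndarray


def shared_partner_distributions(net: Network) -> SharedPartnerDistributions:
    """Tally every unordered dyad by its number of shared partners.

    A shared partner of dyad (i, j) is a node adjacent to both i and j.
    Dyads joined by an edge go to ESP, the rest to NSP; DSP counts all.
    """
    if net.n_nodes < 2:
        raise InvalidInputError("need at least 2 nodes")
    a = net.adjacency(dtype=np.int64)
    sp = a @ a  # sp[i, j] = |N(i) & N(j)| for i != j
    iu = np.triu_indices(net.n_nodes, k=1)
    sp_u = sp[iu]
    edge_u = a[iu].astype(bool)
    nbins = max(net.n_nodes - 1, 1)
    esp = np.bincount(sp_u[edge_u], minlength=nbins)
    nsp = np.bincount(sp_u[~edge_u], minlength=nbins)
    return SharedPartnerDistributions(esp=esp, nsp=nsp, dsp=esp + nsp)


def sum_esp_nsp(esp: Sequence[float], nsp: Sequence[float]) -> np.ndarray:
    """Elementwise ESP + NSP = DSP identity."""
    esp = np.asarray(esp)
    nsp = np.asarray(nsp)
    if esp.shape != nsp.shape:
        raise InvalidInputError("esp and nsp must have equal length")
    return esp + nsp


def gw_weights(tau: float, max_count: int) -> np.ndarray:
    """``w[k] = e^tau (1 - (1 - e^{-tau})^k)`` for k = 0..max_count (w[0] = 0)."""
    if tau < 0:
        raise InvalidInputError("tau must be nonnegative")
    k = np.arange(max_count + 1)
    return np.exp(tau) * (1.0 - (1.0 - np.exp(-tau)) ** k)


def gw_statistic(dist: Sequence[float], tau: float) -> float:
    """Geometrically weighted sum of a count vector with decay ``tau``."""
    dist = np.asarray(dist, dtype=float)
    w = gw_weights(tau, len(dist) - 1) if len(dist) else np.zeros(1)
    return float(np.dot(dist, w[: len(dist)]))


def count_edges(net: Network) -> int:
    return net.n_edges


def count_two_paths(net: Network) -> int:
    """Number of paths of length 2: sum over nodes of C(deg, 2)."""
    d = net.degrees()
    return int((d * (d - 1) // 2).sum())


def count_nodematch(net: Network, attrs: NodeAttributes) -> int:
    """Edges whose endpoints carry the same attribute value."""
    if len(attrs.values) != net.n_nodes:
        raise InvalidInputError("attribute table does not cover all nodes")
    v = attrs.values
    return sum(1 for i, j in net.edges if v[i] == v[j])


def _require_attrs(spec: ModelSpec, attrs: Optional[NodeAttributes]) -> None:
    if spec.needs_attributes() and attrs is None:
        raise InvalidInputError("model contains a nodematch term but no node attributes given")


def statistic_vector(
    net: Network, spec: ModelSpec, attrs: Optional[NodeAttributes] = None
) -> np.ndarray:
    """Evaluate g(y): one statistic per model term, in spec order."""
    _require_attrs(spec, attrs)
    spd = None
    g = np.empty(len(spec))
    for t, term in enumerate(spec.terms):
        if term.kind == "edges":
            g[t] = count_edges(net)
        elif term.kind == "two_path":
            g[t] = count_two_paths(net)
        elif term.kind == "gwd":
            g[t] = gw_statistic(degree_distribution(net), term.tau)
        elif term.kind == "nodematch":
            g[t] = count_nodematch(net, attrs)
        else:
            if spd is None:
                spd = shared_partner_distributions(net)
            dist = getattr(spd, term.kind[2:])
            g[t] = gw_statistic(dist, term.tau)
    return g


def change_statistics(
    net: Network,
    dyad: tuple[int, int],
    spec: ModelSpec,
    attrs: Optional[NodeAttributes] = None,
) -> np.ndarray:
    """Change statistic vector for one dyad.

    Returns ``g(y with the edge present) - g(y with the edge absent)``,
    independent of the dyad's current state, computed incrementally from the
    shared-partner structure around the dyad (never by two full statistic
    evaluations).
    """
    i, j = int(dyad[0]), int(dyad[1])
    if i == j:
        raise InvalidInputError("change statistic undefined for a self-loop")
    if not (0 <= i < net.n_nodes and 0 <= j < net.n_nodes):
        raise InvalidInputError("dyad outside node range")
    _require_attrs(spec, attrs)
    from . import _engine

    state = _engine.GraphState.from_network(net, spec, attrs)
    return _engine.delta_one(state, i, j)
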