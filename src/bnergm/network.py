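"""Undirected simple graphs on labelled nodes and their basic structural summaries.

The graph data model mirrors the adjacency-matrix view used throughout the
ERGM literature: an unweighted, undirected simple graph on ``n`` nodes indexed
``0..n-1``, stored as a set of unordered edges ``(i, j)`` with ``i < j``.
Node labels (e.g. anatomical region names) live in a separate table kept by
the file readers; categorical node attributes (e.g. brain lobe) are carried by
:class:`NodeAttributes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Network",
    "NodeAttributes",
    "density",
    "degree_distribution",
    "geodesic_distribution",
    "triad_census",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


def _canonical_edges(edges: Iterable[tuple[int, int]], n_nodes: int) -> tuple[tuple[int, int], ...]:
    seen = set()
    for e in edges:
        i, j = int(e[0]), int(e[1])
        if i == j:
            raise InvalidInputError(f"self-loop at node {i}")
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise InvalidInputError(f"edge ({i},{j}) outside node range 0..{n_nodes - 1}")
        if i > j:
            i, j = j, i
        if (i, j) in seen:
            raise InvalidInputError(f"duplicate edge ({i},{j})")
        seen.add((i, j))
    return tuple(sorted(seen))


@dataclass(frozen=True)
class Network:
    """An undirected simple graph on ``n_nodes`` labelled nodes.

    Parameters
    ----------
    n_nodes
        Number of nodes; node ids are ``0..n_nodes-1``.
    edges
        Iterable of unordered node pairs. Stored canonically with ``i < j``.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise InvalidInputError("n_nodes must be positive")
        object.__setattr__(self, "edges", _canonical_edges(self.edges, self.n_nodes))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_adjacency(cls, a: np.ndarray) -> "Network":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidInputError("adjacency matrix must be square")
        if not np.array_equal(a, a.T):
            raise InvalidInputError("adjacency matrix must be symmetric")
        iu = np.triu_indices(a.shape[0], k=1)
        mask = a[iu] != 0
        edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
        return cls(a.shape[0], edges)

    # -- views -------------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_dyads(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def adjacency(self, dtype=np.uint8) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=dtype)
        if self.edges:
            e = np.asarray(self.edges)
            a[e[:, 0], e[:, 1]] = 1
            a[e[:, 1], e[:, 0]] = 1
        return a

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def has_edge(self, i: int, j: int) -> bool:
        if i > j:
            i, j = j, i
        return (i, j) in set(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class NodeAttributes:
    """One categorical label per node (e.g. anatomical lobe).

    ``values[i]`` is the label of node ``i``; every node must be labelled.
    """

    name: str
    values: tuple

    @classmethod
    def from_mapping(cls, name: str, mapping: Mapping[int, object], n_nodes: int) -> "NodeAttributes":
        missing = [i for i in range(n_nodes) if i not in mapping]
        if missing:
            raise InvalidInputError(f"nodes missing attribute {name!r}: {missing[:5]}")
        return cls(name, tuple(mapping[i] for i in range(n_nodes)))

    def codes(self) -> np.ndarray:
        """Integer codes for the labels (stable under label identity)."""
        uniq = {}
        out = np.empty(len(self.values), dtype=np.int64)
        for i, v in enumerate(self.values):
            out[i] = uniq.setdefault(v, len(uniq))
        return out


# -- structural summaries ---------------------------------------------------

def density(net: Network) -> float:
    """Proportion of the ``n(n-1)/2`` dyads that are edges."""
    if net.n_nodes < 2:
        raise InvalidInputError("density requires at least 2 nodes")
    return net.n_edges / net.n_dyads


def degree_distribution(net: Network) -> np.ndarray:
    """Count vector ``D_k`` = number of nodes with degree ``k``, k = 0..n-1."""
    return np.bincount(net.degrees(), minlength=net.n_nodes)


def geodesic_distances(net: Network) -> np.ndarray:
    """Matrix of shortest-path lengths (np.inf for unreachable pairs), by BFS."""
    a = csr_matrix(net.adjacency())
    return shortest_path(a, method="D", unweighted=True, directed=False)


def geodesic_distribution(net: Network) -> tuple[dict[int, int], int]:
    """Counts of unordered dyads at each finite geodesic distance.

    Returns ``(counts, unreachable)`` where ``counts[d]`` is the number of
    dyads at distance ``d >= 1`` and ``unreachable`` counts disconnected
    dyads (kept as a separate category, never folded into a numeric bin).
    """
    d = geodesic_distances(net)
    iu = np.triu_indices(net.n_nodes, k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)].astype(int)
    counts = {int(k): int(v) for k, v in zip(*np.unique(finite, return_counts=True))}
    return counts, int(np.sum(~np.isfinite(vals)))


def triad_census(net: Network) -> np.ndarray:
    """Counts of node triples containing exactly 0, 1, 2, 3 internal edges.

    Uses the closed-form identities: with ``t`` triangles, ``w`` wedges
    (paths of length 2) and ``m`` edges, the 2-edge triads number ``w - 3t``
    and each edge lies in ``n - 2`` triads.
    """
    n = net.n_nodes
    if n < 3:
        raise InvalidInputError("triad census requires at least 3 nodes")
    a = net.adjacency(dtype=np.int64)
    deg = a.sum(axis=0)
    m = net.n_edges
    t = int(np.trace(a @ a @ a)) // 6
    w = int((deg * (deg - 1) // 2).sum())
    n2 = w - 3 * t
    n1 = m * (n - 2) - 2 * n2 - 3 * t
    total = n * (n - 1) * (n - 2) // 6
    n0 = total - n1 - n2 - t
    return np.array([n0, n1, n2, t], dtype=np.int64)
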