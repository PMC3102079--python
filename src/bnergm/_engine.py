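"""Numba-compiled kernels: incremental change statistics, the Metropolis
dyad-toggle sampler, and the all-dyad design matrix for pseudo-likelihood.

State layout shared by all kernels (modified in place by the sampler):

* ``A``   -- (n, n) uint8 symmetric adjacency, zero diagonal
* ``deg`` -- (n,) int64 degrees
* ``SP``  -- (n, n) int64 shared-partner counts ``|N(i) & N(j)|`` (note that
  ``SP[i, j]`` never depends on the edge (i, j) itself)
* ``attr`` -- (n,) int64 categorical codes (all -1 when unused)
* ``codes`` -- (p,) int64 term codes in the order of stats.TERM_KINDS
* ``vtab`` -- (p, n+1) float64, for gw terms ``vtab[t, k] =
  e^tau (1 - (1 - e^{-tau})^k)`` so the e^tau factor is pre-folded

Change statistics are evaluated relative to the dyad's edge-absent state:
toggling (i, j) adds a shared partner to every dyad (i, b) with b ~ j and
(j, a) with a ~ i, and moves the dyad itself between the ESP and NSP tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .network import Network, NodeAttributes
from .stats import ModelSpec, TERM_CODES, gw_weights, statistic_vector

# term codes (keep in sync with stats.TERM_KINDS)
_EDGES, _TWOPATH, _GWD, _GWESP, _GWNSP, _GWDSP, _NODEMATCH = range(7)


@njit(cache=True)
def _delta(A, deg, SP, attr, codes, vtab, i, j, out):
    """out <- g(edge present) - g(edge absent) for dyad (i, j)."""
    n = A.shape[0]
    present = A[i, j]
    di0 = deg[i] - present
    dj0 = deg[j] - present
    spij = SP[i, j]
    p = codes.shape[0]
    for t in range(p):
        c = codes[t]
        if c == _EDGES:
            out[t] = 1.0
        elif c == _TWOPATH:
            out[t] = di0 + dj0
        elif c == _GWD:
            out[t] = (vtab[t, di0 + 1] - vtab[t, di0]) + (vtab[t, dj0 + 1] - vtab[t, dj0])
        elif c == _NODEMATCH:
            out[t] = 1.0 if attr[i] == attr[j] else 0.0
        elif c == _GWESP:
            out[t] = vtab[t, spij]
        elif c == _GWNSP:
            out[t] = -vtab[t, spij]
        else:  # _GWDSP
            out[t] = 0.0
    # shared-partner increments on dyads incident to i or j
    for b in range(n):
        if b != i and b != j:
            if A[j, b] == 1:  # dyad (i, b) gains shared partner j
                sp0 = SP[i, b] - present
                eb = A[i, b]
                for t in range(p):
                    c = codes[t]
                    if c >= _GWESP and c <= _GWDSP:
                        dv = vtab[t, sp0 + 1] - vtab[t, sp0]
                        if (c == _GWESP and eb == 1) or (c == _GWNSP and eb == 0) or c == _GWDSP:
                            out[t] += dv
            if A[i, b] == 1:  # dyad (j, b) gains shared partner i
                sp0 = SP[j, b] - present
                eb = A[j, b]
                for t in range(p):
                    c = codes[t]
                    if c >= _GWESP and c <= _GWDSP:
                        dv = vtab[t, sp0 + 1] - vtab[t, sp0]
                        if (c == _GWESP and eb == 1) or (c == _GWNSP and eb == 0) or c == _GWDSP:
                            out[t] += dv


@njit(cache=True)
def _toggle(A, deg, SP, i, j):
    n = A.shape[0]
    if A[i, j] == 1:
        A[i, j] = 0
        A[j, i] = 0
        deg[i] -= 1
        deg[j] -= 1
        for b in range(n):
            if A[j, b] == 1 and b != i:
                SP[i, b] -= 1
                SP[b, i] -= 1
            if A[i, b] == 1 and b != j:
                SP[j, b] -= 1
                SP[b, j] -= 1
    else:
        for b in range(n):
            if A[j, b] == 1 and b != i:
                SP[i, b] += 1
                SP[b, i] += 1
            if A[i, b] == 1 and b != j:
                SP[j, b] += 1
                SP[b, j] += 1
        A[i, j] = 1
        A[j, i] = 1
        deg[i] += 1
        deg[j] += 1


@njit(cache=True)
def _sweep(A, deg, SP, attr, codes, vtab, theta, g, rows, cols, n_steps, delta):
    """Run n_steps Metropolis dyad toggles, updating state and g in place."""
    ndyads = rows.shape[0]
    p = codes.shape[0]
    for _ in range(n_steps):
        d = np.random.randint(0, ndyads)
        i = rows[d]
        j = cols[d]
        _delta(A, deg, SP, attr, codes, vtab, i, j, delta)
        lr = 0.0
        for t in range(p):
            lr += theta[t] * delta[t]
        sign = 1.0
        if A[i, j] == 1:
            sign = -1.0
        lr *= sign
        if lr >= 0.0 or np.random.random() < np.exp(lr):
            _toggle(A, deg, SP, i, j)
            for t in range(p):
                g[t] += sign * delta[t]


@njit(cache=True)
def _run_chain(A, deg, SP, attr, codes, vtab, theta, g, rows, cols,
               burn, thin, nsamp, seed, collect_adj):
    np.random.seed(seed)
    p = codes.shape[0]
    n = A.shape[0]
    delta = np.empty(p)
    G = np.empty((nsamp, p))
    n_adj = nsamp if collect_adj else 1
    Aout = np.zeros((n_adj, n, n), dtype=np.uint8)
    _sweep(A, deg, SP, attr, codes, vtab, theta, g, rows, cols, burn, delta)
    for s in range(nsamp):
        _sweep(A, deg, SP, attr, codes, vtab, theta, g, rows, cols, thin, delta)
        for t in range(p):
            G[s, t] = g[t]
        if collect_adj:
            for a in range(n):
                for b in range(n):
                    Aout[s, a, b] = A[a, b]
    return G, Aout


@njit(cache=True)
def _dyad_design(A, deg, SP, attr, codes, vtab, rows, cols):
    ndyads = rows.shape[0]
    p = codes.shape[0]
    X = np.empty((ndyads, p))
    y = np.empty(ndyads)
    delta = np.empty(p)
    for d in range(ndyads):
        i = rows[d]
        j = cols[d]
        _delta(A, deg, SP, attr, codes, vtab, i, j, delta)
        for t in range(p):
            X[d, t] = delta[t]
        y[d] = A[i, j]
    return X, y


# -- python-side wrappers ----------------------------------------------------

def spec_arrays(spec: ModelSpec, n_nodes: int, attrs: Optional[NodeAttributes]):
    p = len(spec)
    codes = np.empty(p, dtype=np.int64)
    vtab = np.zeros((p, n_nodes + 1))
    for t, term in enumerate(spec.terms):
        codes[t] = TERM_CODES[term.kind]
        if term.tau is not None:
            vtab[t] = gw_weights(term.tau, n_nodes)
    if attrs is not None:
        attr = attrs.codes()
    else:
        attr = np.full(n_nodes, -1, dtype=np.int64)
    return codes, vtab, attr


@dataclass
class GraphState:
    """Mutable sampler state for one graph under one model."""

    A: np.ndarray
    deg: np.ndarray
    SP: np.ndarray
    attr: np.ndarray
    codes: np.ndarray
    vtab: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    g: np.ndarray
    spec: ModelSpec
    attrs: Optional[NodeAttributes]

    @classmethod
    def from_network(cls, net: Network, spec: ModelSpec,
                     attrs: Optional[NodeAttributes] = None) -> "GraphState":
        n = net.n_nodes
        A = net.adjacency(dtype=np.uint8)
        ai = A.astype(np.int64)
        SP = ai @ ai
        np.fill_diagonal(SP, 0)
        deg = ai.sum(axis=0)
        codes, vtab, attr = spec_arrays(spec, n, attrs)
        iu = np.triu_indices(n, k=1)
        g = statistic_vector(net, spec, attrs)
        return cls(A=A, deg=deg, SP=SP, attr=attr, codes=codes, vtab=vtab,
                   rows=iu[0].astype(np.int64), cols=iu[1].astype(np.int64),
                   g=g.copy(), spec=spec, attrs=attrs)

    def network(self) -> Network:
        return Network.from_adjacency(self.A)


def delta_one(state: GraphState, i: int, j: int) -> np.ndarray:
    out = np.empty(state.codes.shape[0])
    _delta(state.A, state.deg, state.SP, state.attr, state.codes, state.vtab,
           int(i), int(j), out)
    return out


def sample_chain(state: GraphState, theta: np.ndarray, burn: int, thin: int,
                 nsamp: int, seed: int, collect_adj: bool = False):
    """Advance the chain; returns (G, adjacency stack or None).

    ``state`` is mutated: on return it holds the last retained draw.
    """
    theta = np.ascontiguousarray(np.asarray(theta, dtype=float))
    G, Aout = _run_chain(state.A, state.deg, state.SP, state.attr, state.codes,
                         state.vtab, theta, state.g, state.rows, state.cols,
                         int(burn), int(thin), int(nsamp), int(seed) % (2 ** 31),
                         collect_adj)
    return G, (Aout if collect_adj else None)


def dyad_design(state: GraphState):
    """Change-statistic design matrix over all dyads, plus edge indicators."""
    return _dyad_design(state.A, state.deg, state.SP, state.attr, state.codes,
                        state.vtab, state.rows, state.cols)
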