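"""Independent brute-force reference implementations used only as test
oracles.  Everything here works from first principles (set intersections,
explicit enumeration, networkx) and deliberately shares no code with the
package's computational paths."""

import itertools
import math

import networkx as nx
import numpy as np

from bnergm.network import Network


def random_network(rng, n, p):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return Network.from_adjacency(a + a.T)


def naive_spd(net):
    """ESP/NSP/DSP by looping over dyads with python sets."""
    nbrs = [set() for _ in range(net.n_nodes)]
    for i, j in net.edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    esp = np.zeros(net.n_nodes - 1, dtype=int)
    nsp = np.zeros(net.n_nodes - 1, dtype=int)
    eset = set(net.edges)
    for i, j in itertools.combinations(range(net.n_nodes), 2):
        sp = len(nbrs[i] & nbrs[j])
        if (i, j) in eset:
            esp[sp] += 1
        else:
            nsp[sp] += 1
    return esp, nsp, esp + nsp


def naive_gw(dist, tau):
    return math.exp(tau) * sum(
        (1 - (1 - math.exp(-tau)) ** k) * c for k, c in enumerate(dist)
    )


def naive_statistic_vector(net, spec, attrs=None):
    """Statistic vector via the naive shared-partner and degree tallies."""
    esp, nsp, dsp = naive_spd(net)
    degs = [0] * net.n_nodes
    for i, j in net.edges:
        degs[i] += 1
        degs[j] += 1
    deg_counts = [degs.count(k) for k in range(net.n_nodes)]
    g = []
    for term in spec.terms:
        if term.kind == "edges":
            g.append(len(net.edges))
        elif term.kind == "two_path":
            g.append(sum(d * (d - 1) // 2 for d in degs))
        elif term.kind == "gwd":
            g.append(naive_gw(deg_counts, term.tau))
        elif term.kind == "gwesp":
            g.append(naive_gw(esp, term.tau))
        elif term.kind == "gwnsp":
            g.append(naive_gw(nsp, term.tau))
        elif term.kind == "gwdsp":
            g.append(naive_gw(dsp, term.tau))
        elif term.kind == "nodematch":
            g.append(sum(1 for i, j in net.edges
                         if attrs.values[i] == attrs.values[j]))
    return np.array(g, dtype=float)


def naive_log_partition(spec, theta, n, attrs=None):
    """Second, independent enumeration of log kappa (tiny n only)."""
    dyads = list(itertools.combinations(range(n), 2))
    total = -np.inf
    for r in range(len(dyads) + 1):
        for combo in itertools.combinations(dyads, r):
            g = naive_statistic_vector(Network(n, combo), spec, attrs)
            total = np.logaddexp(total, float(np.dot(theta, g)))
    return total


def naive_triad_census(net):
    eset = set(net.edges)
    out = [0, 0, 0, 0]
    for trio in itertools.combinations(range(net.n_nodes), 3):
        k = sum(1 for pair in itertools.combinations(trio, 2) if pair in eset)
        out[k] += 1
    return out


def nx_geodesic_distribution(net):
    g = net.to_networkx()
    counts = {}
    reached = 0
    for i, lengths in nx.all_pairs_shortest_path_length(g):
        for j, d in lengths.items():
            if j > i:
                counts[d] = counts.get(d, 0) + 1
                reached += 1
    counts.pop(0, None)
    return counts, net.n_dyads - reached
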