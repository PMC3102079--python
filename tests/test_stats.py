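import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnergm.network import InvalidInputError, Network, NodeAttributes
from bnergm.stats import (ModelSpec, ModelTerm, change_statistics, count_edges,
                          count_nodematch, count_two_paths, gw_statistic,
                          shared_partner_distributions, statistic_vector,
                          sum_esp_nsp)

from oracles import naive_spd, naive_statistic_vector, random_network

FULL_SPEC = ModelSpec((
    ModelTerm("edges"), ModelTerm("two_path"), ModelTerm("gwd", tau=0.5),
    ModelTerm("gwesp", tau=0.75), ModelTerm("gwnsp", tau=0.3),
    ModelTerm("gwdsp", tau=0.9), ModelTerm("nodematch", attribute="lobe"),
))


class TestModelTerms:
    @pytest.mark.parametrize("kwargs", [
        {"kind": "gwesp"},                       # gw term without tau
        {"kind": "edges", "tau": 0.5},           # tau on a non-gw term
        {"kind": "gwesp", "tau": -1.0},          # negative decay
        {"kind": "edges", "attribute": "lobe"},  # attribute off nodematch
        {"kind": "nodematch"},                   # nodematch without attribute
        {"kind": "triangles"},                   # unknown statistic
    ])
    def test_invalid_terms_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            ModelTerm(**kwargs)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(InvalidInputError):
            ModelSpec((ModelTerm("edges"), ModelTerm("edges")))


class TestSharedPartnerDistributions:
    def test_triangle(self, triangle):
        spd = shared_partner_distributions(triangle)
        assert spd.esp.tolist() == [0, 3]
        assert spd.nsp.tolist() == [0, 0]
        assert spd.dsp.tolist() == [0, 3]

    def test_four_cycle(self, four_cycle):
        # brute-forced over all 6 dyads: each edge has 0 shared partners,
        # each diagonal non-edge has 2
        spd = shared_partner_distributions(four_cycle)
        assert spd.esp.tolist() == [4, 0, 0]
        assert spd.nsp.tolist() == [0, 0, 2]
        assert spd.dsp.tolist() == [4, 0, 2]

    def test_empty_graph(self):
        spd = shared_partner_distributions(Network(4, ()))
        assert spd.nsp.tolist() == [6, 0, 0]
        assert spd.esp.sum() == 0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(2, 12))
    def test_identities_on_random_graphs(self, seed, n):
        net = random_network(np.random.default_rng(seed), n, 0.4)
        spd = shared_partner_distributions(net)
        esp, nsp, dsp = naive_spd(net)
        assert spd.esp.tolist() == esp.tolist()
        assert spd.nsp.tolist() == nsp.tolist()
        np.testing.assert_array_equal(spd.dsp, spd.esp + spd.nsp)
        assert spd.esp.sum() == net.n_edges
        assert spd.dsp.sum() == net.n_dyads
        # triangle incidence: each triangle contributes one shared partner
        # to each of its three edges
        from bnergm.network import triad_census
        if n >= 3:
            tri = triad_census(net)[3]
            assert (np.arange(len(spd.esp)) * spd.esp).sum() == 3 * tri


class TestSumEspNsp:
    def test_printed_worked_example(self):
        # the canonical six-node illustration's printed distributions:
        # ESP + NSP must reproduce the printed DSP bin by bin
        assert sum_esp_nsp((1, 5, 1, 0, 0), (1, 4, 3, 0, 0)).tolist() == [2, 9, 4, 0, 0]

    def test_zeros_and_triangle(self):
        assert sum_esp_nsp(np.zeros(3), np.zeros(3)).tolist() == [0, 0, 0]
        assert sum_esp_nsp((0, 3), (0, 0)).tolist() == [0, 3]

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            sum_esp_nsp((1, 2), (1, 2, 3))


class TestGwStatistic:
    @pytest.mark.parametrize("tau", [0.1, 0.75, 2.0])
    def test_triangle_esp_cancellation(self, tau):
        # single-shared-partner bin: e^tau * (1 - (1-e^-tau)) = 1 per count
        assert gw_statistic([0, 3], tau) == pytest.approx(3.0)

    def test_zero_dist_and_tau_zero(self):
        assert gw_statistic([0, 0, 0], 1.0) == 0.0
        # tau = 0 counts entities with at least one shared partner
        assert gw_statistic([7, 2, 5, 1], 0.0) == pytest.approx(8.0)

    def test_negative_tau_rejected(self):
        with pytest.raises(InvalidInputError):
            gw_statistic([1, 2], -0.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=2, max_size=8),
           st.floats(0.01, 3.0), st.integers(1, 7))
    def test_monotone_and_bounded(self, dist, tau, bump_at):
        base = gw_statistic(dist, tau)
        bumped = list(dist)
        bumped[min(bump_at, len(dist) - 1)] += 1
        assert gw_statistic(bumped, tau) >= base
        assert base <= math.exp(tau) * sum(dist[1:]) + 1e-9


class TestCounts:
    def test_examples(self, triangle):
        assert count_edges(triangle) == 3
        assert count_two_paths(triangle) == 3
        star = Network(4, ((0, 1), (0, 2), (0, 3)))
        assert count_two_paths(star) == 3

    def test_nodematch(self):
        net = Network(3, ((0, 1), (1, 2)))
        attrs = NodeAttributes("lobe", ("A", "A", "B"))
        assert count_nodematch(net, attrs) == 1

    def test_nodematch_requires_full_cover(self):
        net = Network(3, ((0, 1),))
        with pytest.raises(InvalidInputError):
            count_nodematch(net, NodeAttributes("lobe", ("A", "B")))


class TestStatisticVector:
    def test_examples(self, triangle):
        assert statistic_vector(triangle, ModelSpec.of("edges")).tolist() == [3.0]
        g = statistic_vector(triangle, ModelSpec.of("edges", "gwesp", tau=0.75))
        assert g.tolist() == pytest.approx([3.0, 3.0])
        empty = Network(5, ())
        np.testing.assert_array_equal(
            statistic_vector(empty, ModelSpec.of("edges", "two_path", "gwdsp")),
            np.zeros(3))

    def test_missing_attrs_raises(self, triangle):
        spec = ModelSpec.of("edges", "nodematch", attribute="lobe")
        with pytest.raises(InvalidInputError, match="nodematch"):
            statistic_vector(triangle, spec)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.integers(3, 10))
    def test_matches_naive_all_terms(self, seed, n):
        rng = np.random.default_rng(seed)
        net = random_network(rng, n, 0.4)
        attrs = NodeAttributes("lobe", tuple(rng.integers(0, 3, n).tolist()))
        np.testing.assert_allclose(
            statistic_vector(net, FULL_SPEC, attrs),
            naive_statistic_vector(net, FULL_SPEC, attrs), atol=1e-10)


class TestChangeStatistics:
    def test_edges_term_is_one(self, small_net):
        assert change_statistics(small_net, (0, 4), ModelSpec.of("edges"))[0] == 1.0

    def test_no_shared_partner_created(self):
        empty = Network(3, ())
        d = change_statistics(empty, (0, 1), ModelSpec.of("gwesp", tau=0.75))
        assert d[0] == 0.0

    def test_self_loop_rejected(self, small_net):
        with pytest.raises(InvalidInputError):
            change_statistics(small_net, (2, 2), ModelSpec.of("edges"))

    def test_matches_statistic_difference_all_terms(self):
        """Incremental change statistics equal the brute-force statistic
        vector difference regardless of the dyad's current state."""
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            net = random_network(rng, n, rng.uniform(0.1, 0.8))
            attrs = NodeAttributes("lobe", tuple(rng.integers(0, 2, n).tolist()))
            i, j = sorted(rng.choice(n, 2, replace=False).tolist())
            with_e = set(net.edges) | {(i, j)}
            without_e = set(net.edges) - {(i, j)}
            expected = (statistic_vector(Network(n, tuple(with_e)), FULL_SPEC, attrs)
                        - statistic_vector(Network(n, tuple(without_e)), FULL_SPEC, attrs))
            np.testing.assert_allclose(
                change_statistics(net, (i, j), FULL_SPEC, attrs), expected,
                atol=1e-10)
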