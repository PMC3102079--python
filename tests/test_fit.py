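import math

import numpy as np
import pytest
from scipy.special import logit, logsumexp

from bnergm.fit import (DegeneracyError, MCMCConfig, NonconvergenceError,
                        aic_of, exact_log_partition, exact_mle, mcmc_mle,
                        mple, wald_pvalues, _enum_matrix)
from bnergm.network import InvalidInputError, Network, NodeAttributes, density
from bnergm.stats import ModelSpec, statistic_vector

from oracles import naive_log_partition, random_network

EDGES = ModelSpec.of("edges")
EDGES_GWESP = ModelSpec.of("edges", "gwesp", tau=0.75)


@pytest.fixture
def net6(rng):
    # random 6-node graph with triangles (interior gwesp statistic)
    while True:
        net = random_network(rng, 6, 0.55)
        from bnergm.network import triad_census
        if 0 < triad_census(net)[3] and net.n_edges < net.n_dyads:
            return net


class TestExactLogPartition:
    @pytest.mark.parametrize("theta,n", [(0.7, 5), (-1.2, 6), (0.0, 4)])
    def test_edges_only_closed_form(self, theta, n):
        nd = n * (n - 1) // 2
        assert exact_log_partition(EDGES, np.array([theta]), n) == pytest.approx(
            nd * math.log1p(math.exp(theta)))

    def test_theta_zero_counts_graphs(self):
        assert exact_log_partition(EDGES_GWESP, np.zeros(2), 4) == pytest.approx(
            6 * math.log(2))

    def test_matches_independent_enumeration(self):
        theta = np.array([-0.4, 0.6])
        got = exact_log_partition(EDGES_GWESP, theta, 5)
        assert got == pytest.approx(naive_log_partition(EDGES_GWESP, theta, 5))

    def test_refuses_large_n(self):
        with pytest.raises(InvalidInputError, match="enumeration"):
            exact_log_partition(EDGES, np.array([0.0]), 8)


class TestExactMle:
    def test_edges_only_is_logit_density(self, small_net):
        fit = exact_mle(small_net, EDGES)
        assert fit.theta[0] == pytest.approx(logit(density(small_net)), abs=1e-8)

    def test_half_density_gives_zero(self):
        net = Network(5, ((0, 1), (0, 2), (1, 2), (2, 3), (3, 4)))  # 5/10 dyads
        assert exact_mle(net, EDGES).theta[0] == pytest.approx(0.0, abs=1e-8)

    def test_moment_match(self, net6):
        """At the exact MLE of an exponential family, E[g(Y)] = g(y_obs)."""
        fit = exact_mle(net6, EDGES_GWESP)
        G = _enum_matrix(EDGES_GWESP, 6, None)
        eta = G @ fit.theta
        w = np.exp(eta - logsumexp(eta))
        np.testing.assert_allclose(w @ G, statistic_vector(net6, EDGES_GWESP),
                                   atol=1e-6)

    def test_degenerate_statistic_named(self):
        with pytest.raises(DegeneracyError, match="edges"):
            exact_mle(Network(5, ()), EDGES)


class TestMple:
    def test_edges_only_is_logit_density(self, small_net):
        fit = mple(small_net, EDGES)
        assert fit.theta[0] == pytest.approx(logit(density(small_net)), abs=1e-8)

    def test_dyad_independent_equals_exact_mle(self, rng):
        """Pseudo-likelihood coincides with the likelihood when dyads are
        independent (edges + nodematch)."""
        net = random_network(rng, 6, 0.5)
        attrs = NodeAttributes("lobe", tuple(rng.integers(0, 2, 6).tolist()))
        spec = ModelSpec.of("edges", "nodematch", attribute="lobe")
        f_mple = mple(net, spec, attrs=attrs)
        f_exact = exact_mle(net, spec, attrs=attrs)
        np.testing.assert_allclose(f_mple.theta, f_exact.theta, atol=1e-6)

    def test_separation_raises(self):
        with pytest.raises(NonconvergenceError):
            mple(Network(5, ()), EDGES)


class TestMcmcMle:
    def test_edges_only_matches_closed_form(self, rng):
        net = random_network(rng, 8, 0.4)
        fit = mcmc_mle(net, EDGES, MCMCConfig(seed=5))
        assert fit.theta[0] == pytest.approx(logit(density(net)), abs=0.02)

    def test_matches_exact_mle_n6(self, net6):
        f_ex = exact_mle(net6, EDGES_GWESP)
        f_mc = mcmc_mle(net6, EDGES_GWESP, MCMCConfig(seed=3))
        np.testing.assert_allclose(f_mc.theta, f_ex.theta, atol=0.05)
        # bridge log-likelihood agrees with the enumerated one
        assert f_mc.loglik == pytest.approx(f_ex.loglik, abs=0.1)
        assert f_mc.loglik >= mple_loglik_bound(net6, f_ex) - 1e-6

    def test_seed_determinism(self, net6):
        f1 = mcmc_mle(net6, EDGES_GWESP, MCMCConfig(seed=11, compute_loglik=False))
        f2 = mcmc_mle(net6, EDGES_GWESP, MCMCConfig(seed=11, compute_loglik=False))
        np.testing.assert_array_equal(f1.theta, f2.theta)
        np.testing.assert_array_equal(f1.se, f2.se)


def mple_loglik_bound(net, exact_fit):
    """True log-likelihood evaluated at the MPLE start (enumeration)."""
    th = mple(net, exact_fit.spec).theta
    G = _enum_matrix(exact_fit.spec, net.n_nodes, None)
    g_obs = statistic_vector(net, exact_fit.spec)
    return float(th @ g_obs - logsumexp(G @ th))


class TestWaldAndAic:
    def test_pvalue_examples(self, small_net):
        fit = exact_mle(small_net, EDGES)
        fit.theta = np.array([1.96])
        fit.se = np.array([1.0])
        assert wald_pvalues(fit)[0] == pytest.approx(0.05, abs=1e-3)
        fit.theta = np.array([0.0])
        assert wald_pvalues(fit)[0] == pytest.approx(1.0)
        fit.theta = np.array([3.0])
        assert wald_pvalues(fit)[0] == pytest.approx(0.0027, abs=1e-4)

    def test_zero_se_flagged(self, small_net):
        fit = exact_mle(small_net, EDGES)
        fit.se = np.array([0.0])
        with pytest.raises(InvalidInputError):
            wald_pvalues(fit)

    def test_aic(self):
        assert aic_of(-10.0, 3) == 26.0
        assert aic_of(0.0, 1) == 2.0
        # one extra parameter must buy a log-likelihood unit
        assert aic_of(-9.5, 4) > aic_of(-10.0, 3)
        with pytest.raises(InvalidInputError):
            aic_of(0.0, 0)
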