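import math

import numpy as np
import pytest

from bnergm.fit import NonconvergenceError, mple
from bnergm.network import Network, NodeAttributes
from bnergm.sample import SamplerConfig, simulate_networks
from bnergm.selection import (aic_select, backward_pvalue_select, gof_score,
                              gof_simulate, graphical_select)
from bnergm.stats import ModelSpec, ModelTerm


@pytest.fixture(scope="module")
def clustered_net():
    """One n=40 draw from an edges+gwesp model (has real clustering)."""
    spec = ModelSpec.of("edges", "gwesp", tau=0.75)
    return simulate_networks(spec, [-4.0, 1.2], 40, 1,
                             SamplerConfig(seed=101))[0]


class TestGofSimulate:
    def test_single_simulation(self, clustered_net):
        fit = mple(clustered_net, ModelSpec.of("edges"))
        rep = gof_simulate(clustered_net, fit, n_sim=1, seed=0)
        assert rep.n_sim == 1
        assert all(rep.simulated[f].shape[0] == 1 for f in rep.simulated)

    def test_seed_determinism(self, clustered_net):
        fit = mple(clustered_net, ModelSpec.of("edges"))
        r1 = gof_simulate(clustered_net, fit, n_sim=5, seed=3)
        r2 = gof_simulate(clustered_net, fit, n_sim=5, seed=3)
        for f in r1.simulated:
            np.testing.assert_array_equal(r1.simulated[f], r2.simulated[f])

    def test_refuses_nonconverged(self, clustered_net):
        fit = mple(clustered_net, ModelSpec.of("edges"))
        fit.converged = False
        with pytest.raises(NonconvergenceError):
            gof_simulate(clustered_net, fit, n_sim=2)

    def test_self_consistent_degree_envelope(self):
        """For a network drawn from an edges-only model, simulating from its
        own fitted edges-only model keeps the observed degree distribution
        inside the simulated min-max envelope for >= 90% of non-empty bins."""
        net = simulate_networks(ModelSpec.of("edges"), [-2.0], 40, 1,
                                SamplerConfig(seed=55))[0]
        fit = mple(net, ModelSpec.of("edges"))
        rep = gof_simulate(net, fit, n_sim=100, seed=7)
        obs = rep.observed["degree"]
        sims = rep.simulated["degree"]
        active = (obs > 0) | (sims > 0).any(axis=0)
        inside = ((obs >= sims.min(axis=0)) & (obs <= sims.max(axis=0)))[active]
        assert inside.mean() >= 0.9


class TestGofScore:
    def test_perfect_match_scores_zero(self, clustered_net):
        fit = mple(clustered_net, ModelSpec.of("edges"))
        rep = gof_simulate(clustered_net, fit, n_sim=4, seed=1)
        for f in rep.simulated:
            rep.simulated[f] = np.stack([rep.observed[f]] * 4)
            rep.simulated_totals[f] = np.full(4, rep.observed_totals[f])
        assert gof_score(rep) == 0.0

    def test_invariant_to_duplicating_simulations(self, clustered_net):
        fit = mple(clustered_net, ModelSpec.of("edges"))
        rep = gof_simulate(clustered_net, fit, n_sim=9, seed=2)
        s1 = gof_score(rep)
        for f in rep.simulated:
            rep.simulated[f] = np.concatenate([rep.simulated[f]] * 2)
            rep.simulated_totals[f] = np.concatenate([rep.simulated_totals[f]] * 2)
        assert gof_score(rep) == pytest.approx(s1)

    def test_true_model_beats_null_model(self, clustered_net):
        """On data planted with clustering, the generating family scores
        better than the pure-density model."""
        full = mple(clustered_net, ModelSpec.of("edges", "gwesp", tau=0.75))
        null = mple(clustered_net, ModelSpec.of("edges"))
        s_full = gof_score(gof_simulate(clustered_net, full, n_sim=50, seed=5))
        s_null = gof_score(gof_simulate(clustered_net, null, n_sim=50, seed=5))
        assert s_full < s_null


def test_gof_tsv_export(tmp_path, clustered_net):
    import pandas as pd
    from bnergm.selection import write_gof_tsv

    fit = mple(clustered_net, ModelSpec.of("edges"))
    rep = gof_simulate(clustered_net, fit, n_sim=5, seed=1)
    out = tmp_path / "gof.tsv"
    write_gof_tsv(rep, out)
    df = pd.read_csv(out, sep="\t")
    assert set(df["family"]) == {"degree", "esp", "geodesic", "triad_census"}
    assert (df["sim_min_logit_freq"] <= df["sim_median_logit_freq"]).all()


def test_plot_gof_renders_four_panels(clustered_net):
    import matplotlib
    matplotlib.use("Agg")
    from bnergm.selection import plot_gof

    fit = mple(clustered_net, ModelSpec.of("edges"))
    rep = gof_simulate(clustered_net, fit, n_sim=5, seed=1)
    axes = plot_gof(rep)
    assert len(np.ravel(axes)) == 4


class TestBackwardSelect:
    def test_keeps_significant_full_model(self, clustered_net):
        spec = ModelSpec.of("edges", "gwesp", tau=0.75)
        res = backward_pvalue_select(clustered_net, spec, fitter=mple)
        assert res.spec.names == spec.names
        assert len(res.trail) == 1

    def test_drops_irrelevant_nodematch(self):
        """Random labels carry no signal: the nodematch term should be
        eliminated in nearly all replicates (type-I behaviour)."""
        spec = ModelSpec((ModelTerm("edges"), ModelTerm("nodematch", attribute="x")))
        rng = np.random.default_rng(0)
        dropped = 0
        n_rep = 40
        for r in range(n_rep):
            net = simulate_networks(ModelSpec.of("edges"), [-1.5], 30, 1,
                                    SamplerConfig(seed=1000 + r))[0]
            attrs = NodeAttributes("x", tuple(rng.integers(0, 2, 30).tolist()))
            res = backward_pvalue_select(net, spec, fitter=mple, attrs=attrs)
            if all(t.kind != "nodematch" for t in res.spec.terms):
                dropped += 1
        assert dropped / n_rep >= 0.9

    def test_trail_records_every_fit(self, clustered_net):
        spec = ModelSpec((ModelTerm("edges"), ModelTerm("two_path"),
                          ModelTerm("gwdsp", tau=0.75)))
        res = backward_pvalue_select(clustered_net, spec, fitter=mple)
        assert res.trail[-1]["spec"].names == res.spec.names
        assert all("fit" in rec for rec in res.trail)


class TestAicSelect:
    def test_single_candidate(self, clustered_net):
        res = aic_select(clustered_net, [ModelTerm("edges")], fitter=mple)
        assert res.spec.names == ("edges",)

    def test_recovers_planted_gwesp(self, clustered_net):
        cands = [ModelTerm("edges"), ModelTerm("gwesp", tau=0.75),
                 ModelTerm("gwd", tau=0.75)]
        res = aic_select(clustered_net, cands, fitter=mple)
        assert any(t.kind == "gwesp" for t in res.spec.terms)

    def test_chosen_minimizes_trail(self, clustered_net):
        cands = [ModelTerm("edges"), ModelTerm("gwesp", tau=0.75),
                 ModelTerm("two_path")]
        res = aic_select(clustered_net, cands, fitter=mple)
        best_aic = min(rec["aic"] for rec in res.trail)
        assert res.fit.aic == best_aic


class TestGraphicalSelect:
    def test_deterministic_under_seed(self, clustered_net):
        cands = [ModelTerm("edges"), ModelTerm("gwesp", tau=0.75)]
        r1 = graphical_select(clustered_net, cands, fitter=mple, n_sim=20, seed=9)
        r2 = graphical_select(clustered_net, cands, fitter=mple, n_sim=20, seed=9)
        assert r1.spec.names == r2.spec.names
        assert [rec["score"] for rec in r1.trail] == [rec["score"] for rec in r2.trail]

    def test_chosen_minimizes_score(self, clustered_net):
        cands = [ModelTerm("edges"), ModelTerm("gwesp", tau=0.75),
                 ModelTerm("two_path")]
        res = graphical_select(clustered_net, cands, fitter=mple, n_sim=20, seed=4)
        chosen_score = min(rec["score"] for rec in res.trail
                           if rec["spec"].names == res.spec.names)
        assert chosen_score <= min(rec["score"] for rec in res.trail) + 1e-12
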