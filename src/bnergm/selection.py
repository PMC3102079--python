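"""Model selection for brain-network ERGMs and the simulation-based
goodness-of-fit machinery behind the graphical procedure.

Three procedures are provided, reflecting practice in the applied
literature: backward elimination on Wald p-values, exhaustive minimum-AIC
search, and a graphical goodness-of-fit search that simulates networks from
every candidate fit and scores how well four structural distributions of
the observed network (degree, edgewise shared partners, minimum geodesic
distance, triad census) are reproduced.  The procedures can and do disagree;
the full trail of candidates is recorded so they can be compared side by
side.

The GOF score is a quantification of the visual judgment used with logit
relative-frequency plots: per family and bin, the absolute difference
between the observed logit relative frequency and the median simulated one
(with (count + 0.5)/(total + 1) smoothing), averaged over bins and then
over the four families with equal weight.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .fit import FitResult, NonconvergenceError
from .network import (InvalidInputError, Network, NodeAttributes,
                      degree_distribution, geodesic_distribution, triad_census)
from .sample import SamplerConfig, simulate_networks
from .stats import ModelSpec, ModelTerm, shared_partner_distributions
from . import network as _netmod

__all__ = [
    "GofReport",
    "SelectionResult",
    "gof_simulate",
    "gof_score",
    "backward_pvalue_select",
    "aic_select",
    "graphical_select",
    "gof_report_frame",
    "write_gof_tsv",
    "plot_gof",
]

GOF_FAMILIES = ("degree", "esp", "geodesic", "triad_census")

Fitter = Callable[..., FitResult]


def _family_counts(net: Network) -> dict[str, np.ndarray]:
    """Fixed-length count vectors for the four GOF families.

    Geodesic bins are distances 1..n-1 followed by one unreachable bin.
    """
    n = net.n_nodes
    deg = degree_distribution(net)
    esp = shared_partner_distributions(net).esp
    geo_counts, unreachable = geodesic_distribution(net)
    geo = np.zeros(n, dtype=np.int64)
    for d, c in geo_counts.items():
        geo[d - 1] = c
    geo[-1] = unreachable
    return {
        "degree": deg.astype(np.int64),
        "esp": esp.astype(np.int64),
        "geodesic": geo,
        "triad_census": triad_census(net),
    }


def _family_total(family: str, counts: np.ndarray, n: int) -> int:
    # degrees are over nodes, ESP over that network's edges, geodesic over
    # dyads, triads over node triples
    if family == "degree":
        return n
    if family == "esp":
        return int(counts.sum())
    if family == "geodesic":
        return n * (n - 1) // 2
    return n * (n - 1) * (n - 2) // 6


@dataclass
class GofReport:
    """Observed vs simulated GOF distributions for one fitted model."""

    n_nodes: int
    n_sim: int
    seed: int
    observed: dict[str, np.ndarray]
    simulated: dict[str, np.ndarray]  # family -> (n_sim, n_bins) counts
    observed_totals: dict[str, int]
    simulated_totals: dict[str, np.ndarray]  # family -> (n_sim,)


def gof_simulate(
    net: Network,
    fit: FitResult,
    n_sim: int = 100,
    seed: int = 0,
    attrs: Optional[NodeAttributes] = None,
) -> GofReport:
    """Simulate ``n_sim`` networks at the fitted theta and collect the four
    distribution families for the observed network and every simulation.

    The chain starts from a Bernoulli graph at the observed density.
    """
    if not fit.converged:
        raise NonconvergenceError("refusing GOF simulation from a nonconverged fit")
    if n_sim < 1:
        raise InvalidInputError("n_sim must be >= 1")
    config = SamplerConfig(seed=seed, init=("bernoulli", _netmod.density(net)))
    sims = simulate_networks(fit.spec, fit.theta, net.n_nodes, n_sim, config, attrs)
    obs = _family_counts(net)
    sim_counts = {f: np.stack([_family_counts(s)[f] for s in sims]) for f in GOF_FAMILIES}
    return GofReport(
        n_nodes=net.n_nodes,
        n_sim=n_sim,
        seed=seed,
        observed=obs,
        simulated=sim_counts,
        observed_totals={f: _family_total(f, obs[f], net.n_nodes) for f in GOF_FAMILIES},
        simulated_totals={
            f: np.array([_family_total(f, sim_counts[f][s], net.n_nodes)
                         for s in range(n_sim)])
            for f in GOF_FAMILIES
        },
    )


def _logit_rel_freq(counts: np.ndarray, total) -> np.ndarray:
    """Smoothed logit relative frequency, p = (count + 0.5)/(total + 1)."""
    counts = np.asarray(counts, dtype=float)
    total = np.asarray(total, dtype=float)
    p = (counts + 0.5) / (total + 1.0)
    return np.log(p) - np.log1p(-p)


def gof_score(report: GofReport) -> float:
    """Mean absolute logit discrepancy between observed and median simulated
    relative frequencies, averaged within and then across the four families
    (equal weight); lower is better, 0 means a perfect match."""
    family_scores = []
    for fam in GOF_FAMILIES:
        obs = report.observed[fam]
        sims = report.simulated[fam]
        active = (obs > 0) | (sims > 0).any(axis=0)
        if not active.any():
            continue
        l_obs = _logit_rel_freq(obs, report.observed_totals[fam])
        l_sim = _logit_rel_freq(sims, report.simulated_totals[fam][:, None])
        med = np.median(l_sim, axis=0)
        family_scores.append(float(np.abs(l_obs - med)[active].mean()))
    return float(np.mean(family_scores)) if family_scores else 0.0


@dataclass
class SelectionResult:
    """Chosen model plus the full record of candidates examined."""

    spec: ModelSpec
    fit: FitResult
    trail: list = field(default_factory=list)  # records: dict per candidate


def _fit_or_none(fitter: Fitter, net, spec, attrs):
    try:
        return fitter(net, spec, attrs=attrs), None
    except Exception as exc:  # fit failures are recorded, not fatal
        return None, str(exc)


def backward_pvalue_select(
    net: Network,
    full_spec: ModelSpec,
    alpha: float = 0.05,
    fitter: Optional[Fitter] = None,
    attrs: Optional[NodeAttributes] = None,
) -> SelectionResult:
    """Backward elimination: iteratively drop the least significant term.

    Refits after each drop; the edges term is never dropped (it plays the
    intercept role).  Stops when every remaining p-value is <= alpha, or
    when a refit fails (the previous model is kept).
    """
    from .fit import mple, wald_pvalues

    fitter = fitter or mple
    spec = full_spec
    fit = fitter(net, spec, attrs=attrs)
    trail = []
    while True:
        pvals = wald_pvalues(fit)
        trail.append({"spec": spec, "fit": fit, "p_values": pvals})
        droppable = [(pvals[t], t) for t in range(len(spec))
                     if spec.terms[t].kind != "edges"]
        if not droppable:
            break
        worst_p, worst_t = max(droppable)
        if worst_p <= alpha:
            break
        new_spec = ModelSpec(tuple(t for k, t in enumerate(spec.terms) if k != worst_t))
        new_fit, err = _fit_or_none(fitter, net, new_spec, attrs)
        if new_fit is None:
            trail.append({"spec": new_spec, "fit": None, "error": err})
            break
        spec, fit = new_spec, new_fit
    return SelectionResult(spec=spec, fit=fit, trail=trail)


def _candidate_subsets(candidate_terms: Sequence[ModelTerm]):
    """All subsets of the candidates, each augmented with a forced edges term."""
    others = [t for t in candidate_terms if t.kind != "edges"]
    if len(others) > 11:
        raise InvalidInputError("exhaustive search limited to 12 candidate terms")
    edges = ModelTerm("edges")
    for r in range(len(others) + 1):
        for combo in itertools.combinations(others, r):
            yield ModelSpec((edges,) + combo)


def aic_select(
    net: Network,
    candidate_terms: Sequence[ModelTerm],
    fitter: Optional[Fitter] = None,
    attrs: Optional[NodeAttributes] = None,
) -> SelectionResult:
    """Exhaustive minimum-AIC search over all candidate subsets containing
    edges.  Failed fits are recorded with AIC = +inf."""
    from .fit import mple

    fitter = fitter or mple
    trail = []
    best = None
    for spec in _candidate_subsets(candidate_terms):
        fit, err = _fit_or_none(fitter, net, spec, attrs)
        aic = fit.aic if fit is not None else math.inf
        trail.append({"spec": spec, "fit": fit, "aic": aic, "error": err})
        if fit is not None and (best is None or aic < best[0]):
            best = (aic, spec, fit)
    if best is None:
        raise NonconvergenceError("no candidate model could be fitted")
    return SelectionResult(spec=best[1], fit=best[2], trail=trail)


def graphical_select(
    net: Network,
    candidate_terms: Sequence[ModelTerm],
    fitter: Optional[Fitter] = None,
    n_sim: int = 100,
    seed: int = 0,
    attrs: Optional[NodeAttributes] = None,
) -> SelectionResult:
    """Goodness-of-fit search: over the same subset lattice as
    :func:`aic_select`, simulate from each fitted candidate and return the
    model with the smallest :func:`gof_score`."""
    from .fit import mple

    fitter = fitter or mple
    trail = []
    best = None
    for k, spec in enumerate(_candidate_subsets(candidate_terms)):
        fit, err = _fit_or_none(fitter, net, spec, attrs)
        if fit is None:
            trail.append({"spec": spec, "fit": None, "score": math.inf, "error": err})
            continue
        report = gof_simulate(net, fit, n_sim=n_sim, seed=seed + k, attrs=attrs)
        score = gof_score(report)
        trail.append({"spec": spec, "fit": fit, "score": score, "report": report})
        if best is None or score < best[0]:
            best = (score, spec, fit)
    if best is None:
        raise NonconvergenceError("no candidate model could be fitted")
    return SelectionResult(spec=best[1], fit=best[2], trail=trail)


def gof_report_frame(report: GofReport):
    """Per-bin summary table: observed logit relative frequency and the
    simulated median / min / max per family and bin (active bins only)."""
    import pandas as pd

    rows = []
    for fam in GOF_FAMILIES:
        obs = report.observed[fam]
        sims = report.simulated[fam]
        active = np.flatnonzero((obs > 0) | (sims > 0).any(axis=0))
        l_obs = _logit_rel_freq(obs, report.observed_totals[fam])
        l_sim = _logit_rel_freq(sims, report.simulated_totals[fam][:, None])
        for b in active:
            rows.append({
                "family": fam, "bin": int(b), "observed_count": int(obs[b]),
                "observed_logit_freq": l_obs[b],
                "sim_median_logit_freq": float(np.median(l_sim[:, b])),
                "sim_min_logit_freq": float(l_sim[:, b].min()),
                "sim_max_logit_freq": float(l_sim[:, b].max()),
            })
    return pd.DataFrame(rows)


def write_gof_tsv(report: GofReport, path) -> None:
    gof_report_frame(report).to_csv(path, sep="\t", index=False)


def plot_gof(report: GofReport, axes=None):
    """Boxplot panel of logit relative frequencies, one subplot per family:
    simulated boxplots per bin with the observed statistics as a solid line."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, len(GOF_FAMILIES), figsize=(4 * len(GOF_FAMILIES), 3))
    for ax, fam in zip(np.ravel(axes), GOF_FAMILIES):
        obs = report.observed[fam]
        sims = report.simulated[fam]
        active = np.flatnonzero((obs > 0) | (sims > 0).any(axis=0))
        l_obs = _logit_rel_freq(obs, report.observed_totals[fam])
        l_sim = _logit_rel_freq(sims, report.simulated_totals[fam][:, None])
        ax.boxplot([l_sim[:, b] for b in active], positions=range(len(active)))
        ax.plot(range(len(active)), l_obs[active], "k-", lw=2, label="observed")
        ax.set_xticks(range(len(active)))
        ax.set_xticklabels([str(b) for b in active], fontsize=7)
        ax.set_title(fam)
        ax.set_ylabel("logit relative frequency")
    return axes
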