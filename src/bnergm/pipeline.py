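"""End-to-end pipeline: construct networks from correlation matrices, fit a
model per subject, run the three selection procedures side by side, assess
fit by simulation, summarize descriptive metrics, and optionally compare two
groups.

This module is the library's orchestration layer (the package is used from
Python; every stage is also callable on its own).  All randomness flows from
a single root seed, and every artifact carries an echo of the configuration
so runs are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as bio
from .compare import CohortFits, compare_term
from .construct import DEFAULT_S, threshold_by_s
from .fit import FitResult, MCMCConfig, mcmc_mle, mple, wald_pvalues
from .metrics import descriptive_metrics, summarize_simulations
from .network import InvalidInputError, Network, NodeAttributes
from .selection import (aic_select, backward_pvalue_select, gof_score,
                        gof_simulate, graphical_select)
from .stats import ModelSpec, ModelTerm

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full run.

    Exactly one of ``correlation_csvs`` (thresholded at ``s``) or
    ``edgelists`` supplies the subject networks.  ``group_a`` / ``group_b``
    optionally partition subject indices for the parameter-profile
    comparison.
    """

    out_dir: str
    correlation_csvs: tuple = ()
    edgelists: tuple = ()
    s: float = DEFAULT_S
    tau: float = 0.75
    model: tuple = ("edges", "gwesp", "gwnsp")
    candidate_terms: tuple = ("two_path", "gwesp", "gwnsp", "gwd")
    fitter: str = "mple"  # {"mple", "mcmc"}
    run_selection: bool = True
    n_sim_gof: int = 100
    alpha: float = 0.05
    seed: int = 0
    group_a: tuple = ()
    group_b: tuple = ()
    attribute_tsv: Optional[str] = None
    attribute_name: str = "label"

    def model_spec(self) -> ModelSpec:
        return ModelSpec.of(*self.model, tau=self.tau, attribute=self.attribute_name)

    def candidates(self) -> list[ModelTerm]:
        return list(ModelSpec.of("edges", *self.candidate_terms, tau=self.tau,
                                 attribute=self.attribute_name).terms)


@dataclass
class PipelineResult:
    networks: list
    fits: list
    selection: list
    gof_scores: list
    metric_reports: list
    comparisons: list
    artifacts: list


def _echo(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every configured stage; artifacts are written under ``out_dir``.

    Raises on the first stage failure; artifacts written so far are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    ss = np.random.SeedSequence(int(config.seed) % (2 ** 31))
    seeds = [int(s) % (2 ** 31) for s in ss.generate_state(64)]

    # -- load or construct networks ---------------------------------------
    networks: list[Network] = []
    labels_per_subject = []
    if config.correlation_csvs and config.edgelists:
        raise InvalidInputError("give correlation matrices or edge lists, not both")
    if config.correlation_csvs:
        for p in config.correlation_csvs:
            corr = bio.read_correlation_csv(p)
            net = threshold_by_s(corr, config.s)
            networks.append(net)
            labels_per_subject.append(corr.labels or tuple(map(str, range(corr.n))))
    elif config.edgelists:
        for p in config.edgelists:
            net, labels = bio.read_edgelist(p)
            networks.append(net)
            labels_per_subject.append(labels)
    else:
        raise InvalidInputError("no inputs: give correlation_csvs or edgelists")

    spec = config.model_spec()
    attrs = None
    if spec.needs_attributes() or any(t.kind == "nodematch" for t in config.candidates()):
        if config.attribute_tsv is None:
            term = next(t.name for t in spec.terms if t.kind == "nodematch")
            raise InvalidInputError(
                f"model term {term} needs node attributes but no attribute_tsv given"
            )
        attrs = bio.read_node_attributes(config.attribute_tsv, labels_per_subject[0],
                                         name=config.attribute_name)

    def fitter(net, spec, attrs=None):
        if config.fitter == "mcmc":
            return mcmc_mle(net, spec, MCMCConfig(seed=seeds[1]), attrs=attrs)
        return mple(net, spec, attrs=attrs)

    # -- per-subject fit, selection, GOF, metrics --------------------------
    fits, selections, gof_scores, metric_reports = [], [], [], []
    for k, net in enumerate(networks):
        fit = fitter(net, spec, attrs=attrs)
        fits.append(fit)
        path = out / f"subject{k}_fit.json"
        bio.write_fit_json(fit, path)
        artifacts.append(str(path))

        report = gof_simulate(net, fit, n_sim=config.n_sim_gof,
                              seed=seeds[2 + k], attrs=attrs)
        score = gof_score(report)
        gof_scores.append(score)

        sel_record = None
        if config.run_selection:
            cands = config.candidates()
            full = ModelSpec(tuple(cands))
            sel_p = backward_pvalue_select(net, full, alpha=config.alpha,
                                           fitter=fitter, attrs=attrs)
            sel_a = aic_select(net, cands, fitter=fitter, attrs=attrs)
            sel_g = graphical_select(net, cands, fitter=fitter,
                                     n_sim=config.n_sim_gof,
                                     seed=seeds[32 + k], attrs=attrs)
            sel_record = {"p_value": sel_p, "aic": sel_a, "graphical": sel_g}
            path = out / f"subject{k}_selection.json"
            path.write_text(json.dumps({
                "p_value": list(sel_p.spec.names),
                "aic": list(sel_a.spec.names),
                "graphical": list(sel_g.spec.names),
                "seed": seeds[32 + k],
            }, indent=2))
            artifacts.append(str(path))
        selections.append(sel_record)
        metric_reports.append(descriptive_metrics(net))

    # -- group comparison ---------------------------------------------------
    comparisons = []
    if config.group_a and config.group_b:
        cohort_a = CohortFits(tuple(config.group_a),
                              tuple(fits[i] for i in config.group_a))
        cohort_b = CohortFits(tuple(config.group_b),
                              tuple(fits[i] for i in config.group_b))
        for term in spec.names:
            comparisons.append(compare_term(cohort_a, cohort_b, term))
        path = out / "group_comparison.json"
        path.write_text(json.dumps(
            [dataclasses.asdict(c) for c in comparisons], indent=2))
        artifacts.append(str(path))

    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({
        "config": _echo(config),
        "seed": config.seed,
        "n_subjects": len(networks),
        "gof_scores": gof_scores,
        "metrics": [dataclasses.asdict(m) for m in metric_reports],
    }, indent=2))
    artifacts.append(str(manifest))

    return PipelineResult(
        networks=networks, fits=fits, selection=selections,
        gof_scores=gof_scores, metric_reports=metric_reports,
        comparisons=comparisons, artifacts=artifacts,
    )
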