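"""Cohort comparison via ERGM parameter profiles.

Once every subject's network is fitted with one common model, the vector of
per-subject estimates for a term is treated as data: groups are compared by
an approximate (Welch) two-sample t-test, and a group's averaged profile can
be fed back into the sampler to simulate representative networks.

The estimates' own standard errors are deliberately not propagated into the
between-subject test; the between-subject scatter of the estimates is the
error term.  This matches standard practice but understates uncertainty when
within-subject estimation error rivals between-subject variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .fit import FitResult
from .network import InvalidInputError

__all__ = ["CohortFits", "TermComparison", "compare_term", "average_profile"]


@dataclass(frozen=True)
class CohortFits:
    """Converged fits of one shared model across a cohort of subjects."""

    subject_ids: tuple
    fits: tuple

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.fits) or not self.fits:
            raise InvalidInputError("need one fit per subject, at least one subject")
        names = self.fits[0].spec.names
        for f in self.fits:
            if f.spec.names != names:
                raise InvalidInputError("all cohort fits must share one model")
            if not f.converged:
                raise InvalidInputError("all cohort fits must have converged")

    @property
    def term_names(self) -> tuple:
        return self.fits[0].spec.names

    def thetas(self) -> np.ndarray:
        return np.array([f.theta for f in self.fits])

    def term_estimates(self, term: str) -> np.ndarray:
        names = self.term_names
        if term not in names:
            raise InvalidInputError(f"term {term!r} not in model {names}")
        return self.thetas()[:, names.index(term)]


@dataclass(frozen=True)
class TermComparison:
    term: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    t: float
    df: float
    p: float


def compare_term(a: CohortFits, b: CohortFits, term: str) -> TermComparison:
    """Welch two-sample t-test on the per-subject estimates of one term.

    Means and SEs are the sample mean and standard error of the estimates in
    each cohort; degrees of freedom by Satterthwaite.
    """
    xa = a.term_estimates(term)
    xb = b.term_estimates(term)
    if len(xa) < 2 or len(xb) < 2:
        raise InvalidInputError("need at least 2 subjects per cohort")
    res = sps.ttest_ind(xa, xb, equal_var=False)
    return TermComparison(
        term=term,
        mean_a=float(xa.mean()),
        se_a=float(xa.std(ddof=1) / np.sqrt(len(xa))),
        mean_b=float(xb.mean()),
        se_b=float(xb.std(ddof=1) / np.sqrt(len(xb))),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def average_profile(fits: CohortFits) -> np.ndarray:
    """Elementwise mean of the cohort's theta vectors.

    Intended as input to :func:`bnergm.sample.simulate_networks` to draw
    representative networks for the group.
    """
    return fits.thetas().mean(axis=0)
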