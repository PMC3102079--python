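"""ERGM likelihood machinery: exact enumeration for small graphs, maximum
pseudo-likelihood (MPLE), and Markov-chain Monte Carlo maximum likelihood
(MCMC MLE) with bridge-estimated absolute log-likelihoods.

The model is  P(Y = y) = exp(theta' g(y)) / kappa(theta)  over labelled
simple graphs on n nodes.  Because this is a linear exponential family, the
MLE satisfies the moment condition E_theta[g(Y)] = g(y_obs), which the exact
fitter verifies by enumeration and the MCMC fitter approaches by iterated
importance sampling (Geyer-Thompson).
"""

from __future__ import annotations

import functools
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .network import InvalidInputError, Network, NodeAttributes
from .stats import ModelSpec, ModelTerm, gw_weights, statistic_vector
from . import _engine

__all__ = [
    "FitResult",
    "MCMCConfig",
    "NonconvergenceError",
    "DegeneracyError",
    "ENUMERATION_LIMIT",
    "exact_log_partition",
    "exact_mle",
    "mple",
    "mcmc_mle",
    "wald_pvalues",
    "aic_of",
]

ENUMERATION_LIMIT = 7  # at most 2^21 graphs


class NonconvergenceError(RuntimeError):
    """Raised when an estimation routine cannot produce a valid fit."""


class DegeneracyError(NonconvergenceError):
    """Raised when the observed statistics sit on the boundary of the
    achievable region, a hallmark of ERGM degeneracy."""


@dataclass
class FitResult:
    """Parameter estimates and inferential summaries for one fitted model."""

    spec: ModelSpec
    theta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    aic: float
    method: str  # {"exact", "mple", "mcmc_mle"}
    converged: bool
    loglik_kind: str = "absolute"  # {"absolute", "pseudo"}
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_terms(self) -> int:
        return len(self.spec)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": list(self.spec.names),
                "theta": self.theta.tolist(),
                "se": self.se.tolist(),
                "cov": self.cov.tolist(),
                "loglik": self.loglik,
                "loglik_kind": self.loglik_kind,
                "aic": self.aic,
                "method": self.method,
                "converged": self.converged,
                "p_values": wald_pvalues(self).tolist(),
                "diagnostics": {k: v for k, v in self.diagnostics.items()
                                if isinstance(v, (int, float, str, bool, list))},
            },
            indent=2,
        )


def aic_of(loglik: float, p: int) -> float:
    """Akaike information criterion, 2p - 2*loglik."""
    if p < 1:
        raise InvalidInputError("p must be >= 1")
    return 2.0 * p - 2.0 * loglik


def wald_pvalues(fit: FitResult) -> np.ndarray:
    """Two-sided normal-approximation p-values theta_k / se_k per term."""
    se = np.asarray(fit.se, dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise InvalidInputError("standard errors must be positive and finite")
    z = np.abs(np.asarray(fit.theta) / se)
    return 2.0 * norm.sf(z)


# -- exact enumeration -------------------------------------------------------

def _spec_key(spec: ModelSpec) -> tuple:
    return tuple((t.kind, t.tau, t.attribute) for t in spec.terms)


@functools.lru_cache(maxsize=16)
def _enumerate_stats(n: int, spec_key: tuple, attr_codes: Optional[tuple]) -> np.ndarray:
    """Statistic vectors of every labelled simple graph on n nodes.

    Fully vectorised over the 2^C(n,2) edge bitmasks; rows align with the
    bitmask order, columns with the spec terms.
    """
    spec = ModelSpec(tuple(ModelTerm(k, tau=t, attribute=a) for k, t, a in spec_key))
    m = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    masks = np.arange(2 ** m, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(m)) & 1).astype(np.int8)

    # per-node degree: incidence of dyads on nodes
    inc = np.zeros((m, n), dtype=np.int8)
    inc[np.arange(m), iu[0]] = 1
    inc[np.arange(m), iu[1]] = 1
    deg = bits @ inc  # (G, n)

    # shared partners per dyad: list the (edge, edge) wedges through each k
    eidx = -np.ones((n, n), dtype=np.int64)
    eidx[iu] = np.arange(m)
    eidx = np.maximum(eidx, eidx.T)
    need_sp = any(t.kind in ("gwesp", "gwnsp", "gwdsp") for t in spec.terms)
    if need_sp:
        sp = np.zeros((len(masks), m), dtype=np.int16)
        for d in range(m):
            i, j = iu[0][d], iu[1][d]
            for k in range(n):
                if k != i and k != j:
                    sp[:, d] += bits[:, eidx[i, k]] * bits[:, eidx[j, k]]

    G = np.empty((len(masks), len(spec)))
    for t, term in enumerate(spec.terms):
        if term.kind == "edges":
            G[:, t] = bits.sum(axis=1)
        elif term.kind == "two_path":
            G[:, t] = (deg * (deg - 1) // 2).sum(axis=1)
        elif term.kind == "gwd":
            v = gw_weights(term.tau, n - 1)
            G[:, t] = v[deg].sum(axis=1)
        elif term.kind == "nodematch":
            match = (np.array(attr_codes)[iu[0]] == np.array(attr_codes)[iu[1]]).astype(float)
            G[:, t] = bits @ match
        else:
            v = gw_weights(term.tau, n - 1)
            w = v[sp]
            if term.kind == "gwesp":
                G[:, t] = (bits * w).sum(axis=1)
            elif term.kind == "gwnsp":
                G[:, t] = ((1 - bits) * w).sum(axis=1)
            else:
                G[:, t] = w.sum(axis=1)
    return G


def _check_enum(n: int) -> None:
    if n > ENUMERATION_LIMIT:
        raise InvalidInputError(
            f"exact enumeration limited to n <= {ENUMERATION_LIMIT} (got n = {n})"
        )


def _enum_matrix(spec: ModelSpec, n: int, attrs: Optional[NodeAttributes]) -> np.ndarray:
    attr_codes = tuple(attrs.codes().tolist()) if attrs is not None else None
    if spec.needs_attributes() and attr_codes is None:
        raise InvalidInputError("nodematch term requires node attributes")
    return _enumerate_stats(n, _spec_key(spec), attr_codes)


def exact_log_partition(
    spec: ModelSpec, theta: np.ndarray, n_nodes: int,
    attrs: Optional[NodeAttributes] = None,
) -> float:
    """log kappa(theta) = log sum over all graphs of exp(theta' g(y))."""
    _check_enum(n_nodes)
    G = _enum_matrix(spec, n_nodes, attrs)
    return float(logsumexp(G @ np.asarray(theta, dtype=float)))


def _boundary_terms(g_obs: np.ndarray, G: np.ndarray, spec: ModelSpec) -> list[str]:
    lo, hi = G.min(axis=0), G.max(axis=0)
    return [spec.names[t] for t in range(len(spec))
            if g_obs[t] <= lo[t] or g_obs[t] >= hi[t]]


def exact_mle(
    net: Network, spec: ModelSpec, attrs: Optional[NodeAttributes] = None
) -> FitResult:
    """MLE by direct maximization of the enumerated likelihood (small n)."""
    _check_enum(net.n_nodes)
    G = _enum_matrix(spec, net.n_nodes, attrs)
    g_obs = statistic_vector(net, spec, attrs)
    bad = _boundary_terms(g_obs, G, spec)
    if bad:
        raise DegeneracyError(
            f"observed statistic on the boundary of its range for term(s) {bad}; "
            "the MLE does not exist"
        )

    def nll(theta):
        eta = G @ theta
        return float(logsumexp(eta) - theta @ g_obs)

    def grad(theta):
        eta = G @ theta
        w = np.exp(eta - logsumexp(eta))
        return w @ G - g_obs

    res = minimize(nll, np.zeros(len(spec)), jac=grad, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    theta = res.x
    gnorm = float(np.linalg.norm(grad(theta)))
    if gnorm > 1e-6:
        raise NonconvergenceError(f"exact MLE gradient norm {gnorm:.2e} above tolerance")
    eta = G @ theta
    w = np.exp(eta - logsumexp(eta))
    mu = w @ G
    info = (G - mu).T @ (w[:, None] * (G - mu))  # Fisher information = Cov(g)
    cov = np.linalg.inv(info)
    loglik = float(theta @ g_obs - logsumexp(eta))
    return FitResult(
        spec=spec, theta=theta, se=np.sqrt(np.diag(cov)), cov=cov,
        loglik=loglik, aic=aic_of(loglik, len(spec)), method="exact",
        converged=True, diagnostics={"grad_norm": gnorm},
    )


# -- maximum pseudo-likelihood ----------------------------------------------

def mple(
    net: Network, spec: ModelSpec, attrs: Optional[NodeAttributes] = None
) -> FitResult:
    """Logistic regression of edge indicators on change statistics.

    Exact (equal to the MLE) for dyad-independent models; the standard
    starting point for MCMC MLE otherwise.  Standard errors come from the
    usual logistic information matrix.
    """
    import statsmodels.api as sm

    state = _engine.GraphState.from_network(net, spec, attrs)
    X, y = _engine.dyad_design(state)
    if y.min() == y.max():
        raise NonconvergenceError(
            "all dyads share one state (empty or complete graph): perfect separation"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NonconvergenceError("change-statistic design matrix is rank deficient")
    try:
        model = sm.Logit(y, X)
        res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-12)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise NonconvergenceError(f"pseudo-likelihood fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise NonconvergenceError("pseudo-likelihood Newton iterations did not converge")
    theta = np.asarray(res.params, dtype=float)
    cov = np.asarray(res.cov_params(), dtype=float)
    loglik = float(res.llf)
    return FitResult(
        spec=spec, theta=theta, se=np.sqrt(np.diag(cov)), cov=cov,
        loglik=loglik, aic=aic_of(loglik, len(spec)), method="mple",
        converged=True, loglik_kind="pseudo",
        diagnostics={"n_dyads": int(len(y))},
    )


# -- MCMC maximum likelihood -------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Settings for the Geyer-Thompson iterated importance-sampling MLE.

    Defaults: m = 1000 importance draws per iteration, burn-in of
    10*C(n,2) dyad toggles, thinning of C(n,2) toggles, at most 20 outer
    iterations, stopping when the parameter update falls below 1e-3.
    """

    n_sample: int = 1000
    burn_in: Optional[int] = None  # default 10 * C(n,2)
    thin: Optional[int] = None  # default C(n,2)
    max_iter: int = 20
    tol: float = 1e-3
    step_max: float = 1.0
    final_sample: int = 4000
    seed: int = 0
    ess_floor: float = 0.05  # min effective sample size fraction per update
    bridge_steps: int = 10
    bridge_sample: int = 250
    compute_loglik: bool = True

    def resolved(self, n_nodes: int) -> tuple[int, int]:
        nd = n_nodes * (n_nodes - 1) // 2
        burn = self.burn_in if self.burn_in is not None else 10 * nd
        thin = self.thin if self.thin is not None else nd
        return burn, thin


def _child_seeds(seed: int, count: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed) % (2 ** 31))
    return [int(s) % (2 ** 31) for s in ss.generate_state(count)]


def _ess_fraction(logw: np.ndarray) -> float:
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return float(1.0 / np.sum(w ** 2) / len(w))


def mcmc_mle(
    net: Network,
    spec: ModelSpec,
    config: Optional[MCMCConfig] = None,
    attrs: Optional[NodeAttributes] = None,
) -> FitResult:
    """MCMC maximum likelihood via iterated importance sampling.

    Starting from the MPLE, each outer iteration simulates ``m`` networks at
    the current theta, maximizes the importance-sampling approximation of the
    log-likelihood ratio (shrinking the step whenever the effective sample
    size collapses), and stops once the update is below tolerance.  Standard
    errors come from the inverse of the simulated-statistic covariance
    (the estimated Fisher information); the absolute log-likelihood is
    estimated by stepping-stone bridging from theta = 0, where
    log kappa = C(n,2) log 2 is known, so AICs are comparable across models.
    """
    config = config or MCMCConfig()
    n = net.n_nodes
    burn, thin = config.resolved(n)
    g_obs = statistic_vector(net, spec, attrs)
    start = mple(net, spec, attrs)
    theta = start.theta.copy()
    seeds = _child_seeds(config.seed, config.max_iter + config.bridge_steps + 1)

    converged = False
    G = None
    n_iter = 0
    gamma = 0.0
    gamma_trace = []
    for it in range(config.max_iter):
        n_iter = it + 1
        state = _engine.GraphState.from_network(net, spec, attrs)
        G, _ = _engine.sample_chain(state, theta, burn, thin, config.n_sample,
                                    seeds[it])
        mu_it = G.mean(axis=0)
        sd_it = G.std(axis=0, ddof=1)

        # stepping (Hummel-style): when the observed statistics fall outside
        # the simulated cloud (the MPLE start can be badly biased for
        # transitive graphs), target a pseudo-observation pulled toward the
        # sampled mean just far enough to be attainable; convergence requires
        # the untempered target (gamma = 1)
        lo_q = np.quantile(G, 0.05, axis=0)
        hi_q = np.quantile(G, 0.95, axis=0)
        gamma = 1.0
        for t in range(len(g_obs)):
            d = g_obs[t] - mu_it[t]
            if d > 0 and g_obs[t] > hi_q[t]:
                gamma = min(gamma, (hi_q[t] - mu_it[t]) / d)
            elif d < 0 and g_obs[t] < lo_q[t]:
                gamma = min(gamma, (lo_q[t] - mu_it[t]) / d)
        gamma = float(max(gamma, 0.01))
        gamma_trace.append(gamma)
        g_target = gamma * g_obs + (1.0 - gamma) * mu_it

        # early exit once the sampled mean matches the observed statistics
        # to within two Monte-Carlo standard errors per coordinate
        if gamma == 1.0 and np.all(
                np.abs(mu_it - g_obs) <= 2.0 * sd_it / math.sqrt(len(G)) + 1e-12):
            converged = True
            break

        centred = G - g_target

        def neg_ratio(th, _c=centred, _t0=theta):
            d = th - _t0
            return float(logsumexp(_c @ d) - math.log(len(_c)))

        def neg_ratio_grad(th, _G=G, _t0=theta, _g=g_target):
            d = th - _t0
            lw = _G @ d
            w = np.exp(lw - logsumexp(lw))
            return w @ _G - _g

        # trust region: the importance approximation is only reliable near
        # theta_t, so each update is confined to a box of half-width step_max
        bounds = [(t0 - config.step_max, t0 + config.step_max) for t0 in theta]
        res = minimize(neg_ratio, theta, jac=neg_ratio_grad, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 200})
        theta_new = res.x
        # guard against steps the importance sample cannot support
        for _ in range(10):
            if _ess_fraction(G @ (theta_new - theta)) >= config.ess_floor:
                break
            theta_new = theta + 0.5 * (theta_new - theta)
        step = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if gamma == 1.0 and step < config.tol:
            converged = True
            break

    if G is not None and gamma < 1.0:
        raise DegeneracyError(
            "the observed statistics remain outside the simulated 5-95% range "
            f"after {n_iter} iterations (final stepping factor {gamma:.2f}); "
            "the model is likely degenerate or near-degenerate for this graph"
        )

    if G is None:
        raise NonconvergenceError("no sampling iterations performed")

    # final refinement: one Newton step on a larger fresh sample, which also
    # supplies the Fisher information and the moment-based convergence check
    state = _engine.GraphState.from_network(net, spec, attrs)
    G_fin, _ = _engine.sample_chain(state, theta, burn, thin,
                                    config.final_sample, seeds[config.max_iter])
    info = np.atleast_2d(np.cov(G_fin, rowvar=False))
    mu = G_fin.mean(axis=0)
    try:
        step_vec = np.linalg.solve(info, g_obs - mu)
        theta = theta + step_vec
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NonconvergenceError(f"singular Fisher information: {exc}") from exc
    # moment criterion: sampled mean statistics match the observed ones
    # within Monte-Carlo error (lag-1 autocorrelation-inflated)
    m_f = len(G_fin)
    var = np.maximum(np.diag(info), 1e-300)
    centred_fin = G_fin - mu
    rho = np.array([
        float(np.corrcoef(centred_fin[:-1, t], centred_fin[1:, t])[0, 1])
        if var[t] > 0 else 0.0
        for t in range(len(mu))
    ])
    rho = np.clip(np.nan_to_num(rho), 0.0, 0.95)
    se_mean = np.sqrt(var / m_f * (1 + rho) / (1 - rho))
    moment_ok = bool(np.all(np.abs(g_obs - mu) <= 4.0 * se_mean + 1e-9))
    converged = converged or moment_ok

    loglik = math.nan
    loglik_kind = "absolute"
    if config.compute_loglik:
        log_kappa = _bridge_log_kappa(net, spec, attrs, theta, burn, thin, config,
                                      seeds[config.max_iter + 1:])
        loglik = float(theta @ g_obs - log_kappa)
    aic = aic_of(loglik, len(spec)) if config.compute_loglik else math.nan

    return FitResult(
        spec=spec, theta=theta, se=np.sqrt(np.diag(cov)), cov=cov,
        loglik=loglik, aic=aic, method="mcmc_mle", converged=converged,
        loglik_kind=loglik_kind,
        diagnostics={
            "iterations": n_iter, "seed": int(config.seed),
            "gamma_trace": gamma_trace,
            "n_sample": config.n_sample, "burn_in": burn, "thin": thin,
            "mple_start": start.theta.tolist(),
            "mean_sampled_stats": G_fin.mean(axis=0).tolist(),
            "observed_stats": g_obs.tolist(),
        },
    )


def _bridge_log_kappa(net, spec, attrs, theta, burn, thin, config, seeds) -> float:
    """Stepping-stone estimate of log kappa(theta) from the null theta = 0.

    log kappa(0) = C(n,2) log 2 is known; each stone estimates
    log E_{t_k}[exp((t_{k+1} - t_k)' g)] by simulation at t_k.
    """
    n = net.n_nodes
    nd = n * (n - 1) // 2
    K = config.bridge_steps
    log_kappa = nd * math.log(2.0)
    path = np.linspace(0.0, 1.0, K + 1)
    empty = Network(n, ())
    for k in range(K):
        th_k = path[k] * theta
        d = (path[k + 1] - path[k]) * theta
        state = _engine.GraphState.from_network(empty, spec, attrs)
        G, _ = _engine.sample_chain(state, th_k, burn, thin, config.bridge_sample,
                                    seeds[k])
        log_kappa += float(logsumexp(G @ d) - math.log(len(G)))
    return log_kappa
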