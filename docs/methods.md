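# Methods

## Model and statistics

`bnergm` fits exponential random graph models
`P(Y=y) = exp(θ'g(y))/κ(θ)` over undirected simple graphs on `n` labelled
nodes.  The statistic vocabulary (edges, two-path, GWD, GWESP, GWNSP,
GWDSP, nodematch) is the standard brain-network ERGM set; geometric
weighting uses the statnet-compatible form

    gw(d; τ) = e^τ Σ_{i≥1} [1 − (1 − e^{−τ})^i] d_i

applied to the ESP/NSP/DSP or degree count vector.  `τ` is treated as
fixed and known (default 0.75 for every weighted term, settable per term);
curved-family estimation of `τ` is out of scope.  Raw k-degree and k-cycle
counts are not exposed: the degree distribution enters only through GWD,
which exists precisely to avoid the degeneracy the raw counts cause.

Change statistics δ(y, i, j) = g(y⁺ij) − g(y⁻ij) are computed
incrementally from cached degree and shared-partner tables (a toggle of
(i,j) adds a shared partner to every dyad (i,b) with b ~ j and (j,a) with
a ~ i, and moves the dyad itself between the ESP and NSP tallies).  The
kernels are numba-compiled; a pure-numpy statistic evaluator provides the
independent slow path that the tests compare against brute force.

## Estimation

* **Exact (n ≤ 7).**  All `2^C(n,2)` graphs are enumerated with vectorised
  bit arithmetic; the MLE maximizes the enumerated likelihood with an
  analytic gradient, and the fit is accepted only if the gradient norm
  (equivalently ‖E_θ̂[g] − g_obs‖) is below 1e−6.  Standard errors come
  from the inverse Fisher information Cov_θ̂(g).  If any observed statistic
  sits at the extreme of its attainable range the MLE does not exist and a
  degeneracy error names the offending term.
* **MPLE.**  Logistic regression (statsmodels, Newton) of the edge
  indicators on the change statistics over all `C(n,2)` dyads.  Exact for
  dyad-independent models; used as the MCMC starting point otherwise.
  Perfect separation and rank deficiency raise nonconvergence errors.
* **MCMC MLE.**  Geyer–Thompson iterated importance sampling: at each
  outer iteration `m = 1000` networks are sampled at θ_t (burn-in
  `10·C(n,2)` toggles, thinning `C(n,2)`), and the importance
  approximation of the likelihood ratio is maximized inside a trust box of
  half-width 1.0, with the step shrunk whenever the importance weights'
  effective sample size drops below 5%.  Because the MPLE start can be
  badly biased for strongly transitive graphs, the target statistic is
  tempered Hummel-style: the iteration aims at
  `γ·g_obs + (1−γ)·ḡ_sim` with γ the largest value keeping the target
  inside the sampled 5–95% range; convergence requires γ = 1.  If γ never
  reaches 1 the fit aborts with a degeneracy diagnostic — near-degenerate
  models whose sampled statistics cannot cover the data are reported, not
  silently returned.  A final Newton step on a fresh `4000`-draw sample
  polishes θ̂ and supplies the Fisher information; the fit is flagged
  converged when the sampled mean statistics match the observed ones
  within autocorrelation-inflated Monte-Carlo error.
* **Absolute log-likelihood.**  `log κ(θ̂)` is bridged from θ = 0 (where
  `log κ = C(n,2) log 2`) by 10 stepping stones of 250 draws each, so AIC
  values are comparable across models.  MPLE reports the pseudo-likelihood
  and is flagged as such.

## Sampling

A Metropolis chain over uniformly proposed dyad toggles with acceptance
`min(1, exp(±θ'δ))`.  Defaults: burn-in `10·C(n,2)` toggles, thinning
`C(n,2)`; initial state empty for de-novo simulation and Bernoulli at the
observed density for goodness-of-fit simulation.  All chains are
deterministic under a seed.  A tie/no-tie proposal would mix faster on
sparse graphs and is noted as an extension.  Draws whose mean density is
below 0.01 or above 0.99 trigger a degeneracy warning.

## Network construction

Subject networks are built from correlation matrices by an edge-budget
threshold: mean degree `K = n^(1/s)` (from `n = K^s`), edge count
`E = round(nK/2)`, and the `E` largest off-diagonal entries become edges
(signed correlations by default — functional connectivity thresholding
retains positive couplings — with an `absolute=True` option; ties broken
by index order).  Default `s = 2.5`, which gives `K ≈ 6.05` at `n = 90`.

## Selection and goodness of fit

Three procedures over candidate statistics (edges always forced in, since
without it density is unidentified): backward elimination on Wald p-values
(α = 0.05), exhaustive minimum-AIC search over all subsets (≤ 12
candidates), and a graphical GOF search.  GOF simulates `n_sim = 100`
networks at θ̂ and compares four distributions — degree (over nodes),
edgewise shared partners (over that network's edges), geodesic distances
(over dyads, with unreachable dyads a separate bin), triad census (over
triples).  The score quantifies the usual visual judgment of
logit-relative-frequency plots: per bin,
`|logit p_obs − median_sims logit p_sim|` with smoothing
`p = (count + 0.5)/(total + 1)`, averaged over active bins and then over
the four families with equal weight.  Equal weighting is a choice; the
relative scientific importance of the four families is genuinely open, and
the full per-candidate reports are retained so other weightings can be
applied afterwards.

## Group comparison

Per-subject estimates under one shared model are treated as data: Welch
(unequal-variance) t-tests with Satterthwaite degrees of freedom compare
groups term by term — the safer choice for 5-versus-5 cohorts.  The
estimates' own standard errors are *not* propagated; when within-subject
estimation error rivals between-subject spread the test is conservative in
level but understates uncertainty about the group means.  Averaged
profiles can be fed back into the sampler for representative networks.

## Synthetic worlds

* **Cohorts** (`generate_cohort`): per subject θ_s = θ + N(0, sd) per
  term, one network per subject.  Default `n = 90` nodes,
  `θ = (−3.0, 0.5, −0.05)` for edges+GWESP+GWNSP — tuned once (seed 42,
  200 draws) to give mean degree ≈ 5 with the sign pattern real
  resting-state fits show (sparse, clustered, shared-partner-poor
  non-edges); default between-subject sd `(0.4, 0.15, 0.03)`.
* **Modular world** (`modular_model`/`MODULAR_THETA`): six equal "lobes"
  with a strong same-lobe nodematch term,
  `θ = (−5.2, 0.3, −0.02, 4.4)` — tuned once (seed 42, 20 draws) to
  reproduce cortical metric ranges (C ≈ 0.5, L ≈ 4, K ≈ 7.7, almost no
  disconnected pairs).  Carrying the clustering through the
  dyad-independent nodematch term keeps sampling far from the GWESP
  degeneracy ridge, where a three-term model with the same clustering
  level is bimodal and unusable.
* **Correlation matrices** (`generate_corr_matrices`): block-structured
  within/between-module levels plus symmetric Gaussian noise, clipped to
  [−1, 1] with unit diagonal.  Defaults (0.25 / 0.05, noise sd 0.12) are
  set so the `s = 2.5` thresholded graphs are small-world-like and
  connected (C ≈ 0.38, L ≈ 4.8, Eglob ≈ 0.29 at n = 90); only the ratio
  (within − between)/noise matters for which edges survive.  What these
  matrices do *not* emulate: negative partial correlations, spatial
  autocorrelation, heteroscedastic noise, or any time-series structure —
  a green test establishes pipeline correctness on modular small-world
  inputs, not fMRI realism.  Note that such thresholded modular graphs
  are themselves near-degenerate targets for the three-term model at
  τ = 0.75 (observed transitivity sits outside what the model can cover
  at matching density), which the MCMC fitter reports honestly; the
  pipeline therefore defaults to MPLE fits for them.

## Descriptive metrics

Clustering coefficient (mean local transitivity, 0 for degree < 2),
characteristic path length (mean geodesic over *reachable* pairs, with the
unreachable count reported alongside), global efficiency (mean 1/distance
over all pairs, 0 when unreachable), local efficiency (mean global
efficiency of neighbour subgraphs), mean nodal degree.  Cross-checked
against networkx in the tests.

## Numerical choices and limitations

* Nodes are 0-based contiguous integers; readers map arbitrary labels.
* Threshold ties break by (row, col) order; relabeling invariance holds up
  to ties.
* Exact enumeration refuses n > 7 (2^21 graphs).
* All randomness flows from explicit integer seeds (< 2^31); identical
  seeds give byte-identical results.
* Single-site toggling mixes slowly in strongly clustered regimes; the
  sampler is not a perfect sampler and metastable parameter regions
  (bimodal edge counts) remain out of reach for reliable estimation —
  they are detected and reported rather than fitted.
* Directed and weighted graphs are out of scope.
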