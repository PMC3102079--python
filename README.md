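# bnergm — exponential random graph models for whole-brain networks

`bnergm` models whole-brain functional connectivity graphs with exponential
random graph models (ERGMs, also called p\* models).  It is written for
network neuroscientists who want to go beyond one-number descriptions
(clustering coefficient, path length, degree distribution) and ask how a
*set* of interacting local features jointly produces the global architecture
of a brain network — and to simulate, select among, and statistically
compare such models across subjects and groups.

## The model

An undirected simple graph `y` on `n` labelled nodes (brain regions) is
modelled as

```
P(Y = y) = exp(θ' g(y)) / κ(θ)
```

where `g(y)` is a vector of network statistics and `κ(θ)` normalizes over
all graphs on `n` nodes.  Each coefficient `θ_k` is the change in the log
odds of an edge per unit increase of the corresponding statistic.  The
implemented statistics are

| statistic | meaning |
|---|---|
| edges | number of edges (density / intercept term) |
| two_path | number of paths of length 2, Σ_v C(deg v, 2) |
| GWD(τ) | geometrically weighted degree counts |
| GWESP(τ) | geometrically weighted edgewise shared partners (clustering) |
| GWNSP(τ) | geometrically weighted non-edgewise shared partners |
| GWDSP(τ) | geometrically weighted dyadwise shared partners |
| nodematch | edges joining nodes with the same categorical label |

with the geometric weighting `e^τ Σ_{i≥1} [1 − (1 − e^{−τ})^i] d_i` applied
to the relevant count vector `d` (decay `τ` fixed, default 0.75).

The package covers the full workflow:

* **construction** — threshold a (partial-)correlation matrix to a fixed
  edge budget so every subject satisfies `n = K^s` (mean degree
  `K = n^(1/s)`, default `s = 2.5`);
* **fitting** — exact enumeration (n ≤ 7), maximum pseudo-likelihood
  (logistic regression on change statistics), and MCMC maximum likelihood
  (Geyer–Thompson iterated importance sampling with Hummel-style stepping,
  bridge-estimated absolute log-likelihoods, Wald inference);
* **simulation** — Metropolis dyad-toggle sampling from any fitted or
  hypothesized model;
* **selection** — backward p-value elimination, exhaustive minimum-AIC
  search, and a graphical goodness-of-fit search that scores how well
  simulations reproduce the degree, edgewise-shared-partner, geodesic and
  triad-census distributions of the observed network;
* **comparison** — Welch t-tests on per-subject parameter profiles and
  representative networks simulated from a group's averaged profile;
* **synthetic data** — ERGM cohorts with known truth and block-structured
  correlation matrices whose thresholded graphs are small-world-like.

## A worked example

```python
from bnergm import CohortSpec, MCMCConfig, generate_cohort, mcmc_mle, wald_pvalues
from bnergm.stats import ModelSpec

spec = ModelSpec.of("edges", "gwesp", "gwnsp", tau=0.75)
(net, theta_true), = generate_cohort(
    CohortSpec(n_subjects=1, seed=7, between_subject_sd=(0.0, 0.0, 0.0)))
fit = mcmc_mle(net, spec, MCMCConfig(seed=11))
```

Running `examples/02_fit_ergm.py` (which is exactly this) prints

```
simulated subject: 231 edges, mean degree 5.13
generating theta: [-3.    0.5  -0.05]
MPLE estimate:    [-3.042  0.532 -0.051] (logistic-regression start)
MCMC MLE:         [-2.995  0.525 -0.055] +/- [0.282 0.069 0.032]
Wald p-values:    [0.     0.     0.0833]
log-likelihood -804.6 (bridge-estimated), AIC 1615.3, converged=True
```

The estimate recovers the generating profile within one standard error:
the network is sparser than chance (negative edges), more clustered than
chance (positive GWESP), and non-adjacent regions share slightly fewer
partners than chance (negative GWNSP).  The other scripts in `examples/`
walk through shared-partner statistics, network construction and
small-world metrics, the three selection procedures (which genuinely
disagree), and a two-cohort comparison that isolates a planted GWNSP
difference.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a four-subject synthetic cohort of 90-region correlation
matrices from the given seed and runs the full pipeline on it — network
construction, per-subject fits, all three model-selection procedures,
goodness-of-fit simulation and a two-group parameter comparison — then
writes the results manifest to `--out`.
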