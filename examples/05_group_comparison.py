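"""Compare two cohorts via parameter profiles and simulate a representative
network from the averaged profile.

Each subject's network is fitted with one shared model; the per-subject
estimates of a term are then compared across groups with a Welch t-test.
Averaging a group's profiles and simulating from the average gives
"representative" networks for the group."""

import numpy as np

from bnergm import (CohortFits, CohortSpec, SamplerConfig, average_profile,
                    compare_term, descriptive_metrics, generate_cohort, mple,
                    simulate_networks)
from bnergm.stats import ModelSpec

spec = ModelSpec.of("edges", "gwesp", "gwnsp", tau=0.75)

# two cohorts of 5 subjects differing only in the GWNSP parameter
sd = (0.1, 0.05, 0.01)
young = generate_cohort(CohortSpec(n_subjects=5, seed=1, between_subject_sd=sd,
                                   theta=(-3.0, 0.5, -0.10)))
older = generate_cohort(CohortSpec(n_subjects=5, seed=2, between_subject_sd=sd,
                                   theta=(-3.0, 0.5, -0.02)))
fits_a = CohortFits(tuple(range(5)), tuple(mple(n, spec) for n, _ in young))
fits_b = CohortFits(tuple(range(5)), tuple(mple(n, spec) for n, _ in older))

for term in spec.names:
    r = compare_term(fits_a, fits_b, term)
    print(f"{term:12s} group A {r.mean_a:+.3f} (SE {r.se_a:.3f})  "
          f"group B {r.mean_b:+.3f} (SE {r.se_b:.3f})  "
          f"t = {r.t:+.2f}, p = {r.p:.4f}")

profile = average_profile(fits_a)
rep = simulate_networks(spec, profile, 90, 5, SamplerConfig(seed=9))
k = np.mean([descriptive_metrics(n).mean_degree for n in rep])
print(f"\nrepresentative networks from group A's averaged profile "
      f"{np.round(profile, 3)}: mean degree {k:.2f}")
# A small p-value only for the term that actually differs shows the
# profile comparison isolates the planted group difference.
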