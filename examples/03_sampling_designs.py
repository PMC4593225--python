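"""Draw the two epidemiological designs from one simulated cohort.

The classical design pools all disease cases with controls sampled from
the never-diseased (including those who died disease-free); the
incidence-density design matches each case at its onset age to controls
still at risk at that exact age.
"""

import numpy as np

from ccbias import (
    DISEASE_LATE_BASELINE,
    ScenarioConfig,
    sample_classical,
    sample_incidence_density,
    simulate_cohort,
)

config = ScenarioConfig(
    maf=0.25, irr_disease=1.5, irr_death=0.5,
    disease_baseline=DISEASE_LATE_BASELINE, rarity_target=0.22,
    n_individuals=10_000,
)
cohort = simulate_cohort(config, np.random.default_rng(1))

cc = sample_classical(cohort, ratio=5, rng=np.random.default_rng(2))
print(f"classical: {cc.n_cases} cases, {cc.n_controls} controls "
      f"(at most 5 per case; fewer when the never-diseased run out)")

md = sample_incidence_density(cohort, m=5, rng=np.random.default_rng(3))
sizes = [len(c) for c in md.control_genotypes]
multi = np.bincount(np.concatenate(md.control_indices))
print(f"incidence-density: {len(md)} matched sets "
      f"({md.n_dropped_sets} dropped for empty risk sets)")
print(f"  controls per set: min {min(sizes)}, max {max(sizes)}")
print(f"  individuals serving as controls more than once: {(multi > 1).sum()}")

print()
print("Risk-set sampling reuses individuals across sets and allows future")
print("cases as controls; excluding them would bias the rate-ratio estimate.")
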