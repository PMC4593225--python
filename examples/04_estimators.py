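"""Fit both association estimators to one cohort's designs.

Logistic regression on the classical sample estimates the per-allele odds
ratio of *being* diseased; conditional logistic regression on the matched
sample estimates the per-allele incidence rate ratio of *becoming*
diseased. With a protective death allele the two diverge.
"""

import numpy as np

from ccbias import (
    DISEASE_LATE_BASELINE,
    ScenarioConfig,
    analytic_or,
    fit_conditional_logistic,
    fit_logistic,
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
cc = sample_classical(cohort, rng=np.random.default_rng(2))
md = sample_incidence_density(cohort, rng=np.random.default_rng(3))

est_or = fit_logistic(cc)
est_or_age = fit_logistic(cc, adjust_age=True)
est_irr = fit_conditional_logistic(md)

print(f"true IRR of disease:            1.500")
print(f"classical OR:                   {est_or.estimate:.3f} "
      f"(se of log estimate {est_or.std_err:.3f})")
print(f"classical OR, age-adjusted:     {est_or_age.estimate:.3f}")
print(f"incidence-density IRR:          {est_irr.estimate:.3f} "
      f"(se of log estimate {est_irr.std_err:.3f})")
print(f"analytic large-sample OR:       {np.exp(analytic_or(config)):.3f}")
print()
print("The classical OR sits far above the true IRR because the allele also")
print("extends life: carriers accumulate both more disease and more survival,")
print("which inflates their share among cases relative to controls. The")
print("matched estimate recovers the rate ratio the cohort was simulated with.")
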