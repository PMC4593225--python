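# Full study grid: 2 disease baselines x 2 rarity targets x 3 MAFs x
# 8 disease IRRs x 10 death IRRs = 960 scenarios, 1000 replicate cohorts of
# 10,000 individuals each. This is a multi-day single-CPU run; use
# smoke.yaml for a quick end-to-end check.
maf: [0.1, 0.25, 0.5]
irr_disease: [0.5, 1.0, 1.1, 1.2, 1.5, 1.7, 2.0, 3.0]
irr_death: [0.5, 0.75, 0.9, 1.0, 1.1, 1.2, 1.5, 1.7, 2.0, 3.0]
disease_baselines:
  - {mode: 25.0, shape: 0.95, parameterization: rate}
  - {mode: 50.0, shape: 0.1, parameterization: rate}
death_baseline: {mode: 85.0, shape: 0.0004, parameterization: distribution}
rarity_targets: [0.22, 0.025]
n_individuals: 10000
n_replicates: 1000
censor_age: 90.0
controls_per_case: 5
base_seed: 2015
designs: [classical, classical_age_adjusted, incidence_density]
output: results/grid_full.tsv
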