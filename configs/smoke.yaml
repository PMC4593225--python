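# Minimal end-to-end grid (runs in well under a minute).
maf: [0.25]
irr_disease: [1.0, 1.5]
irr_death: [0.5, 1.0]
disease_baselines:
  - {mode: 50.0, shape: 0.1, parameterization: rate}
death_baseline: {mode: 85.0, shape: 0.0004, parameterization: distribution}
rarity_targets: [0.22]
n_individuals: 2000
n_replicates: 5
censor_age: 90.0
controls_per_case: 5
base_seed: 2015
designs: [classical, incidence_density]
output: results/grid_smoke.tsv
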