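# Canonical P3 condition: newborn (P0) initial layouts, transition
# probabilities solved from the P3 composition at P_VS = 0.6, 100
# replicates.  Run with:  endplatesim simulate --config examples/p3.yaml
geometry:
  region_diameter: 300.0
  site_diameter: 30.0
  n_sites: 100
  min_separation_factor: 0.8
composition:
  initial_ratios: [0.31, 0.17, 0.52]
  n_axons: 9
model:
  variant: vacancy_mediated
  target_ratios: [0.57, 0.18, 0.25]
  p_vs: 0.6
activity:
  n_active: 0
  selection_divisor: 2.0
execution:
  max_iter: 50000
  n_reps: 100
  base_seed: 0
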