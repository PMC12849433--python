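# Example pipeline configuration: simulate the default 269-subject
# cohort and run every stage. Replace the `simulate:` block with an
# `inputs:` block (cohort/intakes/genus_counts/tree/traits paths) to run
# on real tables.
seed: 7
outdir: results/run

simulate:
  n_subjects: 269
  n_genera: 120
  diet_effect_on_mediator: 0.5     # path a, per-SD units
  mediator_effect_on_outcome: 0.4  # path b
  direct_effect: 0.5               # path c'

filter:
  min_prevalence: 0.10
  min_mean_rel_abund: 0.01

associations:
  n_perm: 999

mediation:
  n_sims: 1000

eds_bootstrap: 20
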