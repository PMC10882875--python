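# End-to-end pipeline configuration running on a simulated cohort with a
# planted dependency chain a -> b -> c.
seed: 1
output_dir: trajnet_out

simulation:
  n_participants: 8000
  baseline_hazards:
    a: 0.02
    b: 0.01
    c: 0.02
  dependency_matrix:
    a: {b: 4.0}
    b: {c: 4.0}
  age_entry_range: [45, 55]
  dropout_per_wave: 0.05

exclusions:
  require_followup: true
  require_demographics: true
  min_entry_age: 45

direction:
  alpha: 0.05
  policy: bonferroni_pairs   # or per_pair_n
  alternative: two-sided

matching:
  ratio: 3
  age_caliper: 2
  bootstrap_reps: 1000
  ci_level: 0.95
  min_controls: 1

network:
  max_path_length: 4
  top_k: 10
  age_among: stem            # or chain
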