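schema_version: 1
scenario_id: 6
name: no-temporal-pattern
description: >-
  No subgroups and no temporal pattern: a flat mean with continuous
  subject-level heterogeneity (normal random intercept) and occasion-level
  noise.  Any trajectory subgroups found here are random fluctuations.
n: 500
t: 5
time_start: 1.0
time_step: 1.0
seed: 0
groups:
- weight: 1.0
  beta: [5.0]
  intercept: {dist: normal, sd: 1.0}
  residual_sd: 1.0
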