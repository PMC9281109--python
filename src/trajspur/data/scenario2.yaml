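schema_version: 1
scenario_id: 2
name: different-value-ranges
description: >-
  The range of values differs importantly across subgroups: a steep
  increasing subgroup spans roughly twice the value range of the benchmark
  and carries the largest within-subgroup variation, while a mildly
  increasing and a mildly decreasing subgroup cross each other mid
  follow-up.  Smaller sample (n = 300).
n: 300
t: 5
time_start: 1.0
time_step: 1.0
seed: 0
groups:
- weight: 0.3333333333333333
  beta: [-4.0, 7.0]
  intercept: {dist: normal, sd: 0.5}
  residual_sd: 2.5
- weight: 0.3333333333333333
  beta: [6.5, 0.5]
  intercept: {dist: normal, sd: 0.7}
  residual_sd: 1.5
- weight: 0.3333333333333334
  beta: [9.5, -0.5]
  intercept: {dist: normal, sd: 0.7}
  residual_sd: 1.5
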