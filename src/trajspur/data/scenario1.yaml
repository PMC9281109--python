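schema_version: 1
scenario_id: 1
name: three-distinct-subgroups
description: >-
  Benchmark: three clearly separated trajectory subgroups — one rapidly
  increasing, two parallel decreasing — with small persistent subject
  heterogeneity, so the mixture is crisply identifiable.
n: 500
t: 5
time_start: 1.0
time_step: 1.0
seed: 0
groups:
- weight: 0.3333333333333333
  beta: [-1.0, 3.0]
  intercept: {dist: normal, sd: 0.3}
  residual_sd: 1.4
- weight: 0.3333333333333333
  beta: [10.0, -1.0]
  intercept: {dist: normal, sd: 0.3}
  residual_sd: 1.4
- weight: 0.3333333333333334
  beta: [7.0, -1.0]
  intercept: {dist: normal, sd: 0.3}
  residual_sd: 1.4
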