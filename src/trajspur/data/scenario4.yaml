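schema_version: 1
scenario_id: 4
name: increasing-within-subgroup-variance
description: >-
  Consumption-onset style design: everyone starts at time zero, three
  initially distinct linear trajectories, persistent subject offsets, and
  occasion-level residual SD increasing linearly so subgroup distributions
  overlap towards the end of follow-up.
n: 500
t: 5
time_start: 0.0
time_step: 1.0
seed: 0
groups:
- weight: 0.3333333333333333
  beta: [0.0, 0.5]
  intercept: {dist: normal, sd: 0.85}
  residual_sd: [0.8, 1.2, 1.6, 2.0, 2.4]
- weight: 0.3333333333333333
  beta: [0.0, 2.5]
  intercept: {dist: normal, sd: 0.85}
  residual_sd: [0.8, 1.2, 1.6, 2.0, 2.4]
- weight: 0.3333333333333334
  beta: [0.0, 4.5]
  intercept: {dist: normal, sd: 0.85}
  residual_sd: [0.8, 1.2, 1.6, 2.0, 2.4]
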