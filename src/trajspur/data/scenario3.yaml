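schema_version: 1
scenario_id: 3
name: time-point-specific-overlap
description: >-
  Two increasing parallel subgroups whose distributions largely overlap at
  the first occasions, plus a decreasing subgroup that descends into the
  increasing band by the last occasion.  High within- and between-subgroup
  variability relative to the mean separations.
n: 500
t: 5
time_start: 1.0
time_step: 1.0
seed: 0
groups:
- weight: 0.3333333333333333
  beta: [1.5, 1.0]
  intercept: {dist: normal, sd: 0.6}
  residual_sd: 2.8
- weight: 0.3333333333333333
  beta: [3.8, 1.0]
  intercept: {dist: normal, sd: 0.6}
  residual_sd: 2.8
- weight: 0.3333333333333334
  beta: [13.0, -1.5]
  intercept: {dist: normal, sd: 0.6}
  residual_sd: 2.8
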