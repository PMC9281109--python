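schema_version: 1
scenario_id: 5
name: rainbow-continuum
description: >-
  No subgroups: a uniform continuum of individual trajectories centred on a
  single increasing trend (subject intercepts uniform on a wide band), the
  classic rainbow-effect situation.
n: 500
t: 5
time_start: 1.0
time_step: 1.0
seed: 0
groups:
- weight: 1.0
  beta: [1.0, 1.5]
  intercept: {dist: uniform, halfwidth: 1.6}
  residual_sd: 1.1
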