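name: 2d_fractionation
description: >
  Three range-mode sources on two signatures followed by closed-system
  (Rayleigh) fractionation of the mixture; the sample lies outside the
  mixing polygon and is only reachable through the fractionation shift.
signatures: [I1, I2]
equation: {kind: rayleigh, param: A, var: r}
sources:
  - {name: S1, mode: range, mean: [0.0, 0.0], half_range: [3.0, 4.0]}
  - {name: S2, mode: range, mean: [10.0, 30.0], half_range: [4.0, 3.0]}
  - {name: S3, mode: range, mean: [20.0, 0.0], half_range: [3.0, 4.0]}
aux_params:
  - {name: A, mean: [-5.0, -5.0], sigma: [1.0, 1.0], role: fractionation factor}
aux_vars:
  - {name: r, prior_low: 0.0, prior_high: 1.0}
samples:
  - {id: x, x: [25.0, 25.0], sigma_x: [1.0, 1.0]}
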