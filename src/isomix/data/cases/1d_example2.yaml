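name: 1d_example2
description: >
  Same two-source 1D mixing problem, but the sources are uniform ranges of
  equally probable values (half-ranges 2 and 4) instead of Gaussian points.
signatures: [I1]
equation: {kind: mixing}
sources:
  - {name: S1, mode: range, mean: [2.0], half_range: [2.0]}
  - {name: S2, mode: range, mean: [20.0], half_range: [4.0]}
samples:
  - {id: x, x: [11.0], sigma_x: [0.1]}
true_values:
  f: {S1: 0.5, S2: 0.5}
reference:
  f1_interval: [0.3125, 0.65]
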