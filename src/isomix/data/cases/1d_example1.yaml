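name: 1d_example1
description: >
  Two-source mixing on a single signature with the sources defined as points
  with Gaussian uncertainty; the sample sits at the equal-fraction midpoint.
signatures: [I1]
equation: {kind: mixing}
sources:
  - {name: S1, mode: point, mean: [2.0], sigma: [2.0]}
  - {name: S2, mode: point, mean: [20.0], sigma: [4.0]}
samples:
  - {id: x, x: [11.0], sigma_x: [0.1]}
true_values:
  f: {S1: 0.5, S2: 0.5}
reference:
  analytic_f1: 0.500
  analytic_sigma_f1: 0.124
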