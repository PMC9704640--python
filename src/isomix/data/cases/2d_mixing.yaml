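name: 2d_mixing
description: >
  Three well-separated range-mode sources on two signatures contributing
  equally (1/3 each) to the sample; the textbook solvable 2D mixing problem.
signatures: [I1, I2]
equation: {kind: mixing}
sources:
  - {name: S1, mode: range, mean: [0.0, 0.0], half_range: [1.0, 1.0]}
  - {name: S2, mode: range, mean: [10.0, 30.0], half_range: [2.0, 2.0]}
  - {name: S3, mode: range, mean: [20.0, 0.0], half_range: [2.0, 1.0]}
samples:
  - {id: x, x: [10.0, 10.0], sigma_x: [1.0, 1.0]}
true_values:
  f: {S1: 0.333, S2: 0.333, S3: 0.333}
reference:
  posterior:
    f_S1: {mean: 0.331, median: 0.334, sd: 0.074, ci68: [0.252, 0.411]}
    f_S2: {mean: 0.334, median: 0.336, sd: 0.047, ci68: [0.286, 0.383]}
    f_S3: {mean: 0.335, median: 0.331, sd: 0.077, ci68: [0.253, 0.419]}
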