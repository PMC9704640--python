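name: nitrate_case2
description: >
  Same river nitrate system, but with open-system denitrification of the
  mixed nitrate pool: mu = sum f_i S_i - E r, where E is the denitrification
  fractionation factor and r the reduced nitrate fraction to be estimated.
signatures: [d15N, d18O]
equation: {kind: open_system_reduced, param: E, var: r}
sources:
  - {name: river, mode: point, mean: [5.0, 2.5], sigma: [0.5, 0.5]}
  - {name: fertilizer, mode: point, mean: [-16.5, 11.2], sigma: [0.5, 0.5]}
  - {name: manure, mode: point, mean: [3.0, 4.5], sigma: [3.0, 0.5]}
aux_params:
  - {name: E, mean: [-15.9, -8.0], sigma: [2.0, 2.0], role: fractionation factor}
aux_vars:
  - {name: r, prior_low: 0.0, prior_high: 1.0}
samples:
  - {id: x1_point_B, x: [-8.3, 8.1], sigma_x: [0.5, 0.5]}
  - {id: x2_point_C, x: [1.2, 12.9], sigma_x: [0.5, 0.5]}
true_values:
  f: {river: 0.2, fertilizer: 0.6, manure: 0.2}
  r: {x2_point_C: 0.6}
reference:
  posterior_x1_percent:
    f_river: {mean: 14.8, sd: 9.4}
    f_fertilizer: {mean: 67.1, sd: 9.7}
    f_manure: {mean: 18.1, sd: 11.9}
    r: {mean: 12.5, sd: 9.2}
  posterior_x2_percent:
    f_river: {mean: 19.2, sd: 13.0}
    f_fertilizer: {mean: 56.0, sd: 11.5}
    f_manure: {mean: 24.9, sd: 15.2}
    r: {mean: 56.7, sd: 13.7}
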