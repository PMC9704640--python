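name: nitrate_case1
description: >
  River nitrate source partitioning on (d15N, d18O): upstream river nitrate
  plus fertilizer- and manure-derived nitrate, pure mixing (denitrification
  neglected).  Fertilizer and manure signatures are recalculated from their
  ammonium values through nitrification (d15N shift by eps_nit; nitrate
  oxygen assembled 2:1 from water and atmospheric O2).
signatures: [d15N, d18O]
equation: {kind: mixing}
sources:
  - {name: river, mode: point, mean: [5.0, 2.5], sigma: [0.5, 0.5]}
  - {name: fertilizer, mode: point, mean: [-16.5, 11.2], sigma: [0.5, 0.5]}
  - {name: manure, mode: point, mean: [3.0, 4.5], sigma: [3.0, 0.5]}
samples:
  - {id: x1_point_B, x: [-8.3, 8.1], sigma_x: [0.5, 0.5]}
  - {id: x2_point_C, x: [1.2, 12.9], sigma_x: [0.5, 0.5]}
true_values:
  f: {river: 0.2, fertilizer: 0.6, manure: 0.2}
reference:
  posterior_x1_percent:
    f_river: {mean: 19.5, sd: 11.2}
    f_fertilizer: {mean: 59.4, sd: 5.4}
    f_manure: {mean: 21.2, sd: 12.8}
measured_inputs:
  eps_nitrification: -17.0
  d18O_O2: 23.5
  fertilizer: {d15N_NH4: 0.5, d18O_H2O: 5.0}
  manure: {d15N_NH4: 20.0, d18O_H2O: -5.0}
  river_A: {d18O_H2O: -8.0}
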