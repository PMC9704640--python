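name: n2o
description: >
  3D N2O source partitioning on (d18O, d15N, SP): mixing of four production
  pathways (bacterial denitrification bD, nitrifier denitrification nD,
  fungal denitrification fD, nitrification Ni) followed by Rayleigh
  fractionation during partial reduction to N2 with residual fraction r.
  The three synthetic samples were forward-computed from the range midpoints
  with known fractions; the d18O and SP values of x1/x2 differ from the
  exact midpoint forward values by a few tenths of a permil (the published
  table carries them as printed).
signatures: [d18O, d15N, SP]
equation: {kind: n2o, param: A, var: r}
sources:
  - {name: bD, low: [17.8, -52.8, -5.2], high: [20.6, -42.4, 0.4]}
  - {name: nD, low: [14.4, -60.7, -7.0], high: [17.4, -53.1, 2.8]}
  - {name: fD, low: [43.4, -44.4, 31.0], high: [51.0, -31.2, 36.0]}
  - {name: Ni, low: [21.4, -63.9, 32.0], high: [25.6, -49.3, 36.0]}
aux_params:
  - {name: A, mean: [-15.4, -7.1, -5.9], sigma: [4.7, 2.1, 1.4],
     role: fractionation factor}
aux_vars:
  - {name: r, prior_low: 0.0, prior_high: 1.0}
samples:
  - {id: x1, x: [47.6, -35.2, 11.1], sigma_x: [0.5, 1.0, 1.0]}
  - {id: x2, x: [26.3, -45.0, 3.0], sigma_x: [0.5, 1.0, 1.0]}
  - {id: x3, x: [24.8, -54.0, 31.7], sigma_x: [0.5, 1.0, 1.0]}
true_values:
  f:
    x1: {bD: 0.9, nD: 0.0, fD: 0.1, Ni: 0.0}
    x2: {bD: 0.9, nD: 0.0, fD: 0.1, Ni: 0.0}
    x3: {bD: 0.1, nD: 0.0, fD: 0.0, Ni: 0.9}
  r: {x1: 0.2, x2: 0.8, x3: 0.9}
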