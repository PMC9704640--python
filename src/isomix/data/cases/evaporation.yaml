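name: evaporation
description: >
  Lake evaporative loss from joint (d18O, d2H) of inflowing and outflowing
  water: single source, Craig-Gordon steady-state enrichment as the only
  process; r is the evaporation-to-inflow ratio E/I.  A (humidity and
  temperature dependent slope) and D (limiting enrichment) carry the
  meteorological uncertainty.
signatures: [d18O, d2H]
equation: {kind: craig_gordon}
sources:
  - {name: inflow, mode: point, mean: [-5.0, -34.0], sigma: [0.2, 3.0]}
aux_params:
  - {name: A, mean: [1.7881, 1.5824], sigma: [0.005, 0.03], role: fractionation factor}
  - {name: D, mean: [5.6063, 0.2946], sigma: [0.005, 0.03], role: limiting enrichment}
aux_vars:
  - {name: r, prior_low: 0.0, prior_high: 1.0}
samples:
  - {id: lakewater, x: [-2.0, -25.0], sigma_x: [0.2, 3.0]}
reference:
  closed_form_EI: {d18O: 0.2206, d2H: 0.2248}
  posterior_EI: {mean: 0.2232, ci68: [0.1892, 0.2616]}
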