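name: nitrite
description: >
  Soil nitrite pathway partitioning on (d18O, d15N): production by nitrate
  reduction (NAR), ammonium oxidation (AOX) and organic-N oxidation (ORG),
  consumption split 0.7:0.3 between nitrite reduction (factor A) and nitrite
  oxidation (factor B, inverse fractionation), and oxygen-isotope exchange
  with soil water toward +8.6 permil with exchanged fraction C (d18O only).
signatures: [d18O, d15N]
equation: {kind: nitrite, equil_value: 8.6}
sources:
  - {name: NAR, low: [3.3, -14.3], high: [5.3, -12.3]}
  - {name: AOX, low: [16.4, 65.9], high: [20.4, 71.9]}
  - {name: ORG, low: [16.4, 4.4], high: [20.4, 6.4]}
aux_params:
  - {name: A, mean: [-4.0, -10.0], sigma: [2.0, 2.0], role: fractionation factor}
  - {name: B, mean: [5.0, 13.0], sigma: [2.0, 2.0], role: fractionation factor}
  - {name: C, mean: [0.25, 0.0], sigma: [0.01, 0.0], role: exchange fraction,
     low: 0.0, high: 1.0}
samples:
  - {id: L1, x: [11.8, 3.2], sigma_x: [2.5, 1.9]}
reference:
  posterior:
    f_NAR: {mean: 0.54, sd: 0.17}
    f_AOX: {mean: 0.08, sd: 0.05}
    f_ORG: {mean: 0.37, sd: 0.21}
  tracer_reference:
    f_NAR: {mean: 0.53, sd: 0.20}
    f_AOX: {mean: 0.08, sd: 0.03}
    f_ORG: {mean: 0.39, sd: 0.14}
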