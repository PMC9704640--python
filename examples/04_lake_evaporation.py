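"""Lake evaporation-to-inflow ratio from water isotopes.

The Craig-Gordon steady-state model links the isotopic enrichment of lake
water relative to its inflow to the evaporation/inflow flux ratio E/I.
Inverting it per signature gives two separate point estimates; sampling the
joint two-signature model gives a single E/I with a credible interval that
propagates all input uncertainties.
"""

from isomix import SamplerConfig, invert_evaporation, load_case, run_chain, summarize

case = load_case("evaporation")
x = case.measurements[0].x
S = case.model.source_means()[0]
A = {p.name: p.mean for p in case.model.aux_params}["A"]
D = {p.name: p.mean for p in case.model.aux_params}["D"]

for i, label in enumerate(case.model.signatures.labels):
    r = invert_evaporation(x[i], S[i], A[i], D[i])
    print(f"closed-form E/I from {label}: {r:.4f}")

chain = run_chain(case.model, case.measurements[0],
                  SamplerConfig(chain_length=100_000, seed=1))
row = summarize(chain).table.loc["r"]
print(f"joint posterior E/I: mean = {row['mean']:.4f}, "
      f"CI68 = ({row['ci68_low']:.4f}, {row['ci68_high']:.4f})")

# The two per-signature inversions (~0.221, ~0.225) and the joint posterior
# mean (~0.223) agree; the interval reflects the analytical and
# meteorological (A, D) uncertainties together.
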