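"""N2O production pathways and reduction progress from three signatures.

N2O carries three usable isotope signatures (d18O, d15N and the site
preference SP), enough to partition four production pathways while
simultaneously estimating how much of the N2O was already reduced to N2
(Rayleigh fractionation with residual fraction r).
"""

import numpy as np

from isomix import SamplerConfig, generate_scenario, load_case, run_chain, summarize

case = load_case("n2o")

# forward-check the synthetic sample x2: 90% bacterial + 10% fungal
# denitrification, 80% of the N2O left unreduced
sc = generate_scenario(case.model, [0.9, 0.0, 0.1, 0.0], true_r={"r": 0.8},
                       noise_sd=0.0)
print("forward d15N for x2:", round(float(sc.measurement.x[1]), 1))

chain = run_chain(case.model, case.measurement("x2"),
                  SamplerConfig(chain_length=100_000, seed=1))
table = summarize(chain).table
print(table.loc[["f_bD", "f_nD", "f_fD", "f_Ni", "r"]].round(3))
bd_nd = chain.f[:, 0] + chain.f[:, 1]
print(f"bD + nD combined: mean = {bd_nd.mean():.3f} (truth 0.9)")

# Bacterial and nitrifier denitrification have nearly identical SP and d18O
# ranges, so only their sum is well determined; it recovers the true 0.9
# within ~0.05, and the residual fraction r lands near the true 0.8.
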