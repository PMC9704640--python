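"""River nitrate: source apportionment with and without denitrification.

Fertilizer and manure enter the river as ammonium; nitrification shifts
d15N by the fractionation factor and builds nitrate oxygen from water and
atmospheric O2 in a 2:1 ratio.  Case 1 treats the downstream samples as a
pure mixture of the three recalculated sources; case 2 adds open-system
denitrification and estimates the reduced nitrate fraction r alongside the
mixing fractions.
"""

from isomix import SamplerConfig, load_case, recalc_nitrification_source, run_batch, summarize

d15, d18 = recalc_nitrification_source(d15N_NH4=0.5, eps_nit=-17.0,
                                       d18O_H2O=5.0, d18O_O2=23.5)
print(f"fertilizer recalculated to nitrate: d15N = {d15:.1f}, d18O = {d18:.1f}")

cfg = SamplerConfig(chain_length=100_000, seed=1)

case1 = load_case("nitrate_case1")
for item in run_batch(case1.model, case1.measurements, cfg):
    table = summarize(item.chain).table
    means = ", ".join(f"{v}={table.loc[v, 'mean']:.3f}"
                      for v in ("f_river", "f_fertilizer", "f_manure"))
    print(f"case 1 [{item.sample_id}]: {means}")

case2 = load_case("nitrate_case2")
for item in run_batch(case2.model, case2.measurements, cfg):
    table = summarize(item.chain).table
    print(f"case 2 [{item.sample_id}]: f_fertilizer="
          f"{table.loc['f_fertilizer', 'mean']:.3f}, "
          f"r={table.loc['r', 'mean']:.3f} "
          f"(CI68 {table.loc['r', 'ci68_low']:.2f}-{table.loc['r', 'ci68_high']:.2f})")

# Point B is fertilizer-dominated (~0.6).  Under the denitrification model
# the point-C sample, whose deltas are isotopically heavier, is explained by
# roughly 60% nitrate reduction on top of a similar source mixture.
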