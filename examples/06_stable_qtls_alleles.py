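"""Stable-QTL consensus calling and favorable-allele mining.

Filters scan records at -log10 p > 3, keeps marker-trait pairs supported
by F1 families from at least three testers, types their gene action, and
estimates per-band allele effects ai = carrier mean - overall mean.
"""

import lxthet as lx
from lxthet.simulate import DEFAULT_RESID_SD

cfg = lx.demo_config(seed=7, qtl_spec=[
    lx.QTL(0, "FL", a=0.6 * DEFAULT_RESID_SD["FL"], d=0.0),
    lx.QTL(5, "BW", a=0.0, d=0.6 * DEFAULT_RESID_SD["BW"])])
truth, design, pheno = lx.simulate_dataset(cfg)
means = lx.entry_means(pheno, mode="shrunk")
ca = {t: lx.combining_ability(pheno, design, t) for t in lx.TRAITS}
het = lx.heterosis_table(pheno, design)
ctx = lx.run_all(truth.all_bands(), truth.marker_map, design,
                 means, ca, het, lx.AssocConfig())

sig = lx.filter_significant(ctx.records)
stables = lx.stable_qtls(sig, design, min_testers=3)
print(f"{len(sig)} significant records -> {len(stables)} stable QTLs")
for q in stables:
    print(f"  {q.trait} @ {q.marker}: {q.n_testers} testers, "
          f"effect type {q.effect_type}")

summary = lx.pleiotropy_and_subgenome(stables, truth.marker_map)
print("subgenome counts (A = chr 1-13, D = 14-26):",
      summary["subgenome_counts"])

effects, extremes, tally = lx.favorable_alleles(sig, ctx.combinations, ctx.panels)
if not extremes.empty:
    print("\nper-trait extreme allele effects (trait units):")
    print(extremes.round(3).to_string(index=False))
    print("favorable alleles per tester combination:")
    print(tally.to_string())
# A positive ai on a higher-is-better trait marks a favorable band; for
# micronaire the sign convention flips.
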