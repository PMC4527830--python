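"""Replicative-lifespan comparison of two dissection experiments.

Simulates bud-dissection datasets for a wild-type-like strain (mean lifespan
17.5 generations) and a long-lived mutant (27.5), 40 founding mothers each,
then compares them the way dissection studies are scored: summary statistics
plus a Mann-Whitney U test on the eight data points flanking each
experiment's 50% lifespan point (exact enumeration for 8-vs-8).
"""

from silencescreen import (
    StrainSpec,
    flank8_select,
    make_dissection_set,
    mann_whitney_u,
    percent_change,
    summarize_rls,
)

wt = make_dissection_set(StrainSpec("WT", 17.5), n_mothers=40, seed=101, genotype="WT")
mut = make_dissection_set(StrainSpec("rer1d", 27.5), n_mothers=40, seed=202, genotype="rer1d")

swt, smut = summarize_rls(wt), summarize_rls(mut)
for s in (swt, smut):
    print(f"{s.genotype:>6}: n={s.n_mothers} mean={s.mean_lifespan:.2f} "
          f"median={s.median_lifespan:.1f} max={s.max_lifespan}")

print(f"mean extension:   {percent_change(swt, smut, 'mean'):+.1f}%")
print(f"median extension: {percent_change(swt, smut, 'median'):+.1f}%")
print(f"max extension:    {percent_change(swt, smut, 'max'):+.1f}%")

res = mann_whitney_u(flank8_select(wt), flank8_select(mut), mode="auto")
print(f"flank-8 Mann-Whitney ({res.method}): U={res.statistic:g} p={res.p_value:.4g}")

# With a ~57% difference in true means, the eight flanking points separate
# almost completely and the exact two-sided p lands near the enumeration
# floor (2/12870 ~ 1.6e-4 for full separation of 8 vs 8).
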