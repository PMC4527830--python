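"""Reproductive-lifespan curves and the Mantel-Cox test in worms.

Simulates self-fertilized hermaphrodite cohorts: a wild-type-like group
(mean cessation day 4.5) and a slower-declining mutant group (mean 7.5,
with a stronger late-life matricide hazard).  Sterile animals are excluded;
matricide removes a still-reproducing worm and is treated as right-
censoring.  The curves report the fraction of adults still producing viable
progeny per day of adulthood (day 1 = first egg-laying day).
"""

from silencescreen import (
    build_repro_curve,
    default_matricide_hazard,
    logrank_test,
    make_repro_set,
)

wt = make_repro_set(4.5, default_matricide_hazard(0.05), sterile_frac=0.04,
                    n_worms=85, seed=11, genotype="N2")
mut = make_repro_set(7.5, default_matricide_hazard(0.15), sterile_frac=0.04,
                     n_worms=84, seed=22, genotype="rer-1")

for rs in (wt, mut):
    c = build_repro_curve(rs)  # matricide censored
    frac = dict(c.fractions)
    days = sorted(frac)
    print(f"{c.genotype:>5}: n={c.n_included} "
          f"(sterile excluded {c.n_sterile_excluded}, matricide {c.n_matricide})")
    print("       day:      " + " ".join(f"{d:>5}" for d in days[:9]))
    print("       fraction: " + " ".join(f"{frac[d]:>5.2f}" for d in days[:9]))

res = logrank_test(wt, mut)
print(f"Mantel-Cox: chi2={res.statistic:.2f} p={res.p_value:.3g}")

# The mutant curve stays high through day 6 while the wild type has largely
# ceased; the log-rank p-value quantifies that separation with matricide
# worms contributing to the at-risk sets until their removal.
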