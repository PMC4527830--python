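# silencescreen

Simulation and analysis tools for pooled yeast replicative-aging screens
built on age-dependent loss of transcriptional silencing, together with the
lifespan statistics used to validate candidate longevity genes.

## The problem

Replicative lifespan (RLS) in budding yeast — the number of daughters a
mother cell produces before senescing — is classically measured by
micromanipulation, one mother at a time, which does not scale to a deletion
library. A pooled alternative exploits an age reporter: transcriptional
silencing at the *HML* mating-type locus decays in old mothers, so an
`HML::URA3` reporter switches on late in a mother's life, at roughly 70–100%
of her divisions. On 5-FOA (a counter-selective agent toxic to URA3⁺ cells),
cells that derepress the reporter stop dividing; mutants that stay silenced
longer — putatively long-lived ones — should be over-represented in the
selected pool. Barcoded deletion strains are grown as paired ±5-FOA pools,
sampled at days 6 and 16, and compared per strain by two-channel TAG-array
intensities: Cy3 labels the +5-FOA culture, Cy5 the −5-FOA culture, so a
strain enriched by selection has a **negative** log₂ Cy5:Cy3 ratio. A
parallel control library with the reporter at a constitutively silent locus
(`MEI4::URA3`) exposes false positives whose reporter expression is
stochastically defective rather than age-dependent.

This package is for anyone who wants to reason quantitatively about that
screen design: it provides

* a seeded synthetic-data layer (`silencescreen.strains`) — barcoded
  libraries with planted long-lived and silencing-defective strains,
  per-mother lifespans `T ~ round(Gamma(mean L, CV))`, silencing-loss
  generations `G | T ~ Uniform{⌈0.7T⌉, …, T}` (or a constant per-division
  loss for defective strains), dissection datasets, and worm
  reproductive-span records;
* an exact age × silencing-state cohort simulator of the ±5-FOA pooled
  cultures with serial reseeding (`silencescreen.screen`), in a
  deterministic expected-count mode and a stochastic multinomial mode,
  plus the closed-form clone envelope `2^round(L)` (no selection) vs
  `2^⌈f·round(L)⌉` (selection halts the clone at loss fraction `f`);
* the array layer and hit rule (`silencescreen.arrays`): median-centered
  log₂ Cy5:Cy3 ratios, classification of long-lived candidates (negative at
  both days **and** < −2.3 at day 16), the control-library filter, and
  recovery scoring against planted truth;
* the validation statistics (`silencescreen.spanstats`): RLS summaries and
  a Mann-Whitney U test on the eight data points flanking the 50% lifespan
  point (exact enumeration for small groups), and worm reproductive-span
  curves (sterile worms excluded, matricide right-censored) with the
  Mantel-Cox log-rank test.

## Worked example

`examples/rls_statistics.py` simulates two 40-mother dissection experiments
(true means 17.5 and 27.5 generations) and compares them:

```
    WT: n=40 mean=16.93 median=15.5 max=29
 rer1d: n=40 mean=27.88 median=27.0 max=64
mean extension:   +64.7%
median extension: +74.2%
max extension:    +120.7%
flank-8 Mann-Whitney (mann_whitney_exact): U=0 p=0.0001554
```

The eight values flanking each experiment's 50% point separate completely
(U = 0), so the exact two-sided p-value sits at the enumeration floor,
2/12870 ≈ 1.6 × 10⁻⁴.

`examples/full_screen_run.py` runs the full default-scale screen — 3762
strains, 52 planted long-lived (+40% lifespan), 2% planted
silencing-defective, 0.25 log₂ units of array noise per channel:

```
strains screened:        3762
planted long-lived:      52
classified hits:         0
sensitivity/specificity: 0.000 / 1.000
hit-set enrichment p:    1
defectives flagged by control library: 100.0%
```

The control filter catches every planted defective strain (their constant
per-division loss collapses them under 5-FOA at any reporter locus). The
planted long-lived strains are enriched in the correct direction but far too
weakly to cross the −2.3 threshold: when silencing loss is confined to the
last 30% of each mother's own lifespan and daughters are born rejuvenated,
old cells are an exponentially rare fraction (~2⁻²¹) of a dividing pool, so
the hit list is empty. `docs/methods.md` works through this model property
in detail — it is the central quantitative finding of the simulator.

Other examples: `clone_envelopes.py` (analytic envelopes and the
degenerate-limit oracle), `pooled_screen_minimal.py` (a two-strain screen
end to end), `worm_repro_span.py` (reproductive-span curves and log-rank).

A thin CLI mirrors the library:
`silencescreen simulate|classify|rls-stats|repro-stats|paper-run|fixtures`.

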