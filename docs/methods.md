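# Methods

## The model

Each strain in a barcoded deletion library is described phenomenologically
by a mean replicative lifespan `L` (daughters per mother before senescence)
and a silencing-loss law for the `HML::URA3` age reporter. A mother's
lifespan is `T = round(X)`, `X ~ Gamma(shape 1/cv², scale L·cv²)`, clipped
at 0 — right-skewed, nonnegative, two-parameter, with `cv = 0` collapsing to
`round(L)` exactly. Given `T`, the silencing-loss generation is uniform on
the integer window `{max(1, ⌈lo·T⌉), …, ⌊hi·T⌋}` with `[lo, hi] = [0.70,
1.00]` by default, so a 30-generation mother derepresses somewhere in
divisions 21–30. Strains carrying a *stochastic* silencing defect instead
draw `G ~ Geometric(p)`, `p = 0.2` per division, independent of age — the
class of false positives a constitutively silent control locus (`MEI4`)
is designed to expose, since there the age-dependent law never fires while
the geometric one does.

### Pool dynamics

The pooled culture is a synchronous branching process. Every cell that can
divide does so once per generation; the daughter is born rejuvenated (age 0,
silenced, fresh `(T, G)`), the mother advances one age unit and loses
silencing when her division index reaches `G`. Under 5-FOA a cell that has
derepressed completes no further divisions and is removed at the next step
(a `foa_kill_lag` of tolerated post-loss divisions is available, default 0,
recording the uncertainty about how fast the drug acts); without 5-FOA,
unsilenced cells divide until senescence. Senescent cells remain in the
census — 5-FOA removes reporter-expressing cells, not silent non-dividers —
and pool extinction is declared when no division-capable cells remain.

Rather than tracking cells, the engine tracks cohorts keyed by
(strain, age, state) with four states: silenced/unsilenced ×
dividing/senescent. Each state is an event in the per-cell pair `(T, G)`
— e.g. "silenced and dividing at age a" is `{T ≥ a+1, G ≥ a+1}` — so exact
per-age transition probabilities follow from joint tail tables of `(T, G)`,
computed once per distinct parameter set. The expected-count mode propagates
expectations through these tables (fully deterministic); the multinomial
mode draws cohort transition counts from the same conditional laws, which is
distributionally identical to drawing `(T, G)` per cell at birth. This keeps
a 3762-strain × 160-generation run to seconds while remaining exact.

Serial passage rescales all cohorts to the target size (expected mode:
exact, conserving relative abundances; multinomial mode: a multinomial
bottleneck whose expectation is the exact rescale). The schedule defaults —
10 generations/day (~2.4 h doublings in rich medium), daily reseeding to
10⁶ cells, 16 days, samples at days 6 and 16 — calibrate the day clock of
the protocol to the generation clock of the model; the generations-per-day
constant is exposed in the schedule because the day-6/day-16 contrast
scales with it.

### Clone envelope

The closed form `clone_envelope(L, foa, f)` gives the population a single
founder's clone reaches when it doubles every generation until halted:
`2^round(L)` unselected, `2^⌈f·round(L)⌉` when selection stops it at loss
fraction `f` (e.g. 2²¹ vs 2³⁰ for `L = 30`, `f = 0.7`). In the degenerate
limit (`cv = 0`, window `[1, 1]`) the cohort engine reproduces this closed
form exactly for every `L`; this is the simulator's oracle test.

### Arrays and hit calling

Array intensities are `scale · abundance · e^ε` per channel and barcode,
`ε ~ N(0, (σ·ln2)²)` with `σ = 0.25` log₂ units per channel by default, so
null log₂ ratios have SD `σ√2`. Intensities below 10⁻⁶ of the per-channel
median are floored to keep ratios of extinct strains finite. Channel
assignment: Cy3 = +5-FOA culture (denominator), Cy5 = −5-FOA culture
(numerator) — the only assignment under which selection-enriched
(long-lived) strains land at negative log₂ Cy5:Cy3, matching the
classification rule. Ratios are median-centered per sample ("log₂
normalized"); the hit rule is `ratio(day 6) < 0 ∧ ratio(day 16) < 0 ∧
ratio(day 16) < −2.3`, strict. The control filter flags any strain whose
control-library day-16 |ratio| exceeds a tolerance (default 1.0 log₂ units;
no published numeric criterion exists, so this is a free parameter) and
declassifies it; missing control barcodes are flagged by convention.

### Why the default screen yields an empty hit list

This is a property of the model, not a bug, and it is the simulator's main
quantitative lesson. In an exponentially growing pool the stable age
distribution is ~2⁻ᵃ at age `a`: cells old enough to derepress an
age-gated reporter (age ≥ 0.7·L ≈ 21) are a ~10⁻⁶ fraction of the pool, so
the per-capita 5-FOA removal flux is tiny and dominated by the short-lived
left tail of the lifespan distribution. Measured at the defaults, the
day-16 log₂ contrast between +40%-lifespan strains and wildtype is ≈ 0.005
— direction correct (and strictly ordered by lifespan in the noiseless
expected mode), but ~3 orders of magnitude short of the −2.3 threshold for
any admissible generations-per-day setting. The geometric-loss defective
strains, whose removal hazard acts on the young bulk of the age
distribution, collapse by tens of log₂ units and are all caught by the
control filter. A strong hit-calling signal at an age-gated reporter would
require either silencing loss that is heritable across the mother-daughter
boundary at clone scale (which would instead extinguish the selected pool
within ~L generations) or a loss hazard with mass at young ages; the
rejuvenating per-mother model implemented here admits neither.

### Lifespan statistics

Dissection summaries report mean, sample median (mean of central order
statistics for even n), max, and the empirical survivor curve. The
Mann-Whitney procedure selects the eight sorted values at 1-based positions
`⌈n/2⌉−3 … ⌈n/2⌉+4` (the 4 at-or-below and 4 above the 50% point; ties
resolve by sorted index, and an alternative nearest-by-value selection is
available behind a flag). The exact mode enumerates all `C(n1+n2, n1)` rank
splits with midrank tie handling and reports the two-sided permutation
p-value; `auto` switches to the tie-corrected normal approximation with
continuity correction (via scipy) above group size 10. Two-sided p-values
throughout.

Worm reproductive spans: cessation is the last day with progeny followed by
two observed progeny-free days (later progeny resets the rule; an
unconfirmed tail is right-censored). Sterile animals are excluded from all
denominators. Matricide kills a still-reproducing animal, so matricide
worms are right-censored at their removal day — the least biased desk
choice, since dropping them (available as `matricide="drop"`, matching the
plotted-fraction convention) discards information and understates late
reproduction. Curves are Kaplan-Meier over cessation; the group test is the
standard 1-df Mantel-Cox log-rank via lifelines, with a hand-worked O−E
table as the test-suite oracle.

## Synthetic data vs real data

The generators emulate the *structure* of the study's datasets — library
size 3762 with 52 planted long-lived strains at +40% lifespan, ≥40-mother
dissection sets, worm cohorts with sterile (4%) and matricide outcomes, a
matricide hazard that is zero before day 5 and constant after — but not
real biology: labels are phenomenological, lifespan dispersion (CV 0.35)
and worm-span dispersion (CV 0.30) are modelling choices because no
per-individual variances are published for these designs, effect sizes
enter as clean multiplicative shifts, and array noise is i.i.d.
log-normal with no probe chemistry, cross-hybridization, or UPTAG/DOWNTAG
redundancy. Passing tests therefore certify the pipeline's arithmetic and
the model's internal consistency, not recovery performance on real screen
data.

## Numerical choices

* Lifespan pmf truncated at 10⁻¹² tail mass and renormalized; integer
  window edges computed with a 10⁻⁹ guard against float round-up of exact
  multiples (so ⌈0.7·30⌉ is 21, never 22).
* Expected-count extinction uses a 10⁻⁹-cell threshold on division-capable
  cells; multinomial mode uses exact zero.
* Exact Mann-Whitney refuses enumerations beyond 2×10⁶ splits.
* Trajectory/array TSVs are written with fixed float formats so reruns are
  byte-identical; every stage seed derives from the master seed via
  `SeedSequence` and is recorded in the run manifest.

## Known limitations

* No nutrient, chronological-aging, stationary-phase, or mating-type
  biology; transformation attrition of the source library is taken as
  given.
* The expected-count mode propagates means, not covariances: strain-level
  drift at small bottlenecks appears only in multinomial mode.
* One TAG per strain; the control and query libraries share identical
  strain parameters apart from the reporter locus.
* The empty default hit list (above) means recovery sensitivity is
  degenerate at the published threshold; recovery statistics become
  informative only at much looser thresholds or stronger planted effects.
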