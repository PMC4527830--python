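"""Pooled ±5-FOA culture simulation with serial reseeding.

The pool is a mixture of barcoded strains kept continually dividing by daily
passage into fresh medium.  Every cell carries a replicative lifespan ``T``
(divisions until senescence; daughters are born rejuvenated at age 0) and a
silencing-loss generation ``G``: the division index at which the reporter
locus derepresses.  For age-dependent strains ``G`` is uniform over the last
~30% of the mother's own lifespan; for stochastic-defect strains it is the
first success of a constant per-division trial.  Under 5-FOA, a cell that has
derepressed the URA3 reporter completes no further divisions and is removed
at the next step (a configurable lag of tolerated post-loss divisions records
the ambiguity of how fast the drug acts).

Two execution modes share one cohort engine.  Cohorts are keyed by
(strain, replicative age, state) with states

* ``SD`` silenced, still able to divide,
* ``SS`` silenced, senescent,
* ``UD`` unsilenced, still able to divide,
* ``US`` unsilenced, senescent.

Because each of these states is an event in the per-cell pair ``(T, G)``,
the exact per-age transition probabilities follow from the joint law of
``(T, G)``; the expected-count mode propagates expectations through those
probabilities, and the multinomial mode draws cohort transition counts from
the same conditional laws, which is distributionally identical to drawing
``(T, G)`` per cell at birth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .strains import Library, StrainSpec, loss_window, _ceil_tol

__all__ = [
    "Schedule",
    "PoolState",
    "AbundanceTrajectory",
    "PoolExtinctionError",
    "clone_envelope",
    "step_generation",
    "reseed",
    "run_screen",
]

_TINY = 1e-300
_TAIL_MASS = 1e-12  # truncation point of the discretised lifespan law


class PoolExtinctionError(RuntimeError):
    """Raised when counter-selection empties the pool."""


@dataclass(frozen=True)
class Schedule:
    """Culture schedule: generations per day, passaging, and sampling days.

    The published protocol gives days (samples at day 6 and day 16 of a
    16-day run) but not generations elapsed per day; ``generations_per_day``
    is the calibration constant tying the two clocks together (default 10,
    i.e. ~2.4 h doublings in rich medium).
    """

    generations_per_day: int = 10
    reseed_interval_days: int = 1
    reseed_target_size: float = 1e6
    sampling_days: tuple[int, ...] = (6, 16)
    total_days: int = 16
    foa_kill_lag: int = 0

    def __post_init__(self) -> None:
        if self.generations_per_day < 1 or self.reseed_interval_days < 1:
            raise ValueError("generations_per_day and reseed_interval_days must be >= 1")
        if self.reseed_target_size <= 0:
            raise ValueError("reseed_target_size must be positive")
        if self.total_days < 1:
            raise ValueError("total_days must be >= 1")
        if self.foa_kill_lag < 0:
            raise ValueError("foa_kill_lag must be >= 0")
        for d in self.sampling_days:
            if not (0 <= d <= self.total_days):
                raise ValueError(f"sampling day {d} outside [0, {self.total_days}]")


def clone_envelope(mean_lifespan: float, foa_on: bool, loss_fraction: float = 0.70) -> int:
    """Closed-form clone-level population envelope.

    Without counter-selection a founder whose clone doubles once per
    generation reaches ``2**round(L)`` cells by its mean lifespan ``L``.
    With 5-FOA the clone is halted at the silencing-loss generation
    ``g = ceil(loss_fraction * round(L))`` and reaches ``2**g``; at the
    earliest loss point (70% of a 30-generation lifespan) that is ``2**21``
    against ``2**30`` unselected.
    """
    if not (np.isfinite(mean_lifespan) and mean_lifespan > 0):
        raise ValueError("mean_lifespan must be positive")
    L = int(round(mean_lifespan))
    if not foa_on:
        return 2**L
    if not (0 < loss_fraction <= 1):
        raise ValueError("loss_fraction must lie in (0, 1]")
    return 2 ** _ceil_tol(loss_fraction * L)


# ---------------------------------------------------------------------------
# per-strain transition tables
# ---------------------------------------------------------------------------

def _lifespan_pmf(mean: float, cv: float) -> np.ndarray:
    """Discretised (rounded) lifespan pmf over 0..K, truncated at tiny tail mass."""
    if cv == 0:
        k = int(round(mean))
        pmf = np.zeros(k + 1)
        pmf[k] = 1.0
        return pmf
    shape = 1.0 / cv**2
    scale = mean * cv**2
    kmax = int(math.ceil(stats.gamma.ppf(1 - _TAIL_MASS, shape, scale=scale)))
    edges = np.arange(kmax + 2) - 0.5
    cdf = stats.gamma.cdf(edges, shape, scale=scale)
    pmf = np.diff(cdf)
    pmf[pmf < 0] = 0.0
    return pmf / pmf.sum()


@dataclass
class _StrainTables:
    """Exact per-age cohort transition probabilities for one parameter set."""

    tSD: np.ndarray  # SD(a) -> SD(a+1)
    tUD: np.ndarray  # SD(a) -> UD(a+1)  (lost silencing at division a+1)
    tSS: np.ndarray  # SD(a) -> SS(a+1)  (senesced silenced)
    tUS: np.ndarray  # SD(a) -> US(a+1)
    rUD: np.ndarray  # UD(a) -> UD(a+1); complement goes to US(a+1)
    pT1: float       # P(a newborn can divide at all)
    max_age: int


def _build_tables(spec: StrainSpec, reporter: str, n_ages: int) -> _StrainTables:
    """Joint-(T, G) tail tables -> transition probabilities, padded to n_ages."""
    pmf = _lifespan_pmf(spec.mean_lifespan, spec.lifespan_cv)
    K = len(pmf) - 1
    b = np.arange(n_ages + 2)

    S1 = np.zeros(n_ages + 2)  # S1[b] = P(T >= b, G >= b)
    S2 = np.zeros(n_ages + 2)  # S2[b] = P(T >= b+1, G = b)
    S3 = np.zeros(n_ages + 2)  # S3[b] = P(T = b, G >= b+1)
    S4 = np.zeros(n_ages + 2)  # S4[b] = P(T = b, G = b)
    W1 = np.zeros(n_ages + 2)  # W1[a] = P(T >= a+1, G <= a)
    W2 = np.zeros(n_ages + 2)  # W2[a] = P(T >= a+2, G <= a)

    # P(T >= k) for k = 0..n_ages+3, zero beyond the pmf support
    PTge = np.zeros(n_ages + 4)
    tail = np.cumsum(pmf[::-1])[::-1]
    m = min(n_ages + 4, K + 1)
    PTge[:m] = tail[:m]
    pmf_pad = np.zeros(n_ages + 2)
    m = min(n_ages + 2, K + 1)
    pmf_pad[:m] = pmf[:m]

    if spec.silencing_defect:
        # G ~ Geometric(p) on 1, 2, ...; independent of T; strikes at any locus
        p, q = spec.defect_loss_p, 1.0 - spec.defect_loss_p
        qpow = q ** np.maximum(b - 1, 0)  # q^(b-1)
        S1[0] = 1.0
        S1[1:] = PTge[1 : n_ages + 2] * qpow[1:]
        S2[1:] = PTge[2 : n_ages + 3] * p * qpow[1:]
        S3 = pmf_pad * q**b  # P(G >= b+1) = q^b
        S4[1:] = pmf_pad[1:] * p * qpow[1:]
        W1 = PTge[1 : n_ages + 3] * (1.0 - q**b)
        W2 = PTge[2 : n_ages + 4] * (1.0 - q**b)
    elif reporter == "mei4":
        # constitutively silent control locus: silencing never ages away
        S1 = PTge[: n_ages + 2].copy()
        S3 = pmf_pad.copy()
    else:
        # age-dependent loss: G | T uniform on the integer window within [lo, hi]*T;
        # G <= T always, so a silenced cell can never senesce (S3 = 0)
        S1[0] = 1.0
        bb = b[1:]
        for T in range(1, K + 1):
            w = pmf[T]
            if w <= 0:
                continue
            g0, g1 = loss_window(spec, T)
            width = g1 - g0 + 1
            PGge = np.where(bb <= g0, 1.0, np.clip((g1 - bb + 1) / width, 0.0, 1.0))
            PGeq = np.where((bb >= g0) & (bb <= g1), 1.0 / width, 0.0)
            PGle = np.clip((bb - g0 + 1) / width, 0.0, 1.0)
            S1[1:] += w * PGge * (bb <= T)
            S2[1:] += w * PGeq * (bb <= T - 1)
            if T <= n_ages + 1:
                S4[T] += w * PGeq[T - 1]  # PGeq is indexed by bb starting at 1
            W1[1:] += w * PGle * (bb <= T - 1)  # age a = bb, requires T >= a+1
            W2[1:] += w * PGle * (bb <= T - 2)

    na = n_ages
    den = S1[1 : na + 1]
    safe = den > _TINY
    tSD = np.where(safe, np.divide(S1[2 : na + 2], den, where=safe, out=np.zeros(na)), 0.0)
    tUD = np.where(safe, np.divide(S2[1 : na + 1], den, where=safe, out=np.zeros(na)), 0.0)
    tSS = np.where(safe, np.divide(S3[1 : na + 1], den, where=safe, out=np.zeros(na)), 0.0)
    tUS = np.where(safe, np.divide(S4[1 : na + 1], den, where=safe, out=np.zeros(na)), 0.0)
    w1 = W1[:na]
    w2 = W2[:na]
    safe_w = w1 > _TINY
    rUD = np.where(safe_w, np.divide(w2, w1, where=safe_w, out=np.zeros(na)), 0.0)
    return _StrainTables(
        tSD=tSD, tUD=tUD, tSS=tSS, tUS=tUS, rUD=rUD, pT1=float(PTge[1]), max_age=K
    )


def _support_max(spec: StrainSpec) -> int:
    return len(_lifespan_pmf(spec.mean_lifespan, spec.lifespan_cv)) - 1


def _table_key(spec: StrainSpec, reporter: str) -> tuple:
    return (
        spec.mean_lifespan,
        spec.lifespan_cv,
        spec.loss_frac_lo,
        spec.loss_frac_hi,
        spec.silencing_defect,
        spec.defect_loss_p,
        reporter if not spec.silencing_defect else "any",
    )


# ---------------------------------------------------------------------------
# pool state
# ---------------------------------------------------------------------------

class PoolState:
    """Age-and-silencing structured counts for every strain in the pool.

    Counts are expected (float) in ``expected`` mode and integer in
    ``multinomial`` mode.  Use :meth:`initialize` to seed a pool with equal
    abundance per strain at age 0, silenced.
    """

    def __init__(
        self,
        library: Library,
        foa_on: bool,
        mode: str,
        reporter: str = "hml",
        foa_kill_lag: int = 0,
    ) -> None:
        if mode not in ("expected", "multinomial"):
            raise ValueError("mode must be 'expected' or 'multinomial'")
        if reporter not in ("hml", "mei4"):
            raise ValueError("reporter must be 'hml' or 'mei4'")
        self.library = library
        self.foa_on = bool(foa_on)
        self.mode = mode
        self.reporter = reporter
        self.foa_kill_lag = int(foa_kill_lag)
        self.time_generations = 0
        self.barcodes = library.barcode_ids

        S = len(library)
        n_ages = max(_support_max(s) for s in library.strains)
        self.n_ages = n_ages
        cache: dict[tuple, _StrainTables] = {}
        tabs = []
        for s in library.strains:
            key = _table_key(s, reporter)
            if key not in cache:
                cache[key] = _build_tables(s, reporter, n_ages)
            tabs.append(cache[key])
        self.tSD = np.stack([t.tSD for t in tabs])
        self.tUD = np.stack([t.tUD for t in tabs])
        self.tSS = np.stack([t.tSS for t in tabs])
        self.tUS = np.stack([t.tUS for t in tabs])
        self.rUD = np.stack([t.rUD for t in tabs])
        self.pT1 = np.array([t.pT1 for t in tabs])

        shape = (S, n_ages + 1)
        self.SD = np.zeros(shape)
        self.SS = np.zeros(shape)
        self.US = np.zeros(shape)
        self.UD: list[np.ndarray] = [np.zeros(shape)]

    # -- construction -----------------------------------------------------

    @classmethod
    def initialize(
        cls,
        library: Library,
        total_cells: float,
        foa_on: bool,
        mode: str = "expected",
        reporter: str = "hml",
        foa_kill_lag: int = 0,
        rng: Optional[np.random.Generator] = None,
    ) -> "PoolState":
        st = cls(library, foa_on, mode, reporter, foa_kill_lag)
        S = len(library)
        if mode == "expected":
            per = np.full(S, total_cells / S)
        else:
            rng = rng or np.random.default_rng()
            per = rng.multinomial(int(round(total_cells)), np.full(S, 1.0 / S)).astype(float)
        if mode == "expected":
            st.SD[:, 0] = per * st.pT1
            st.SS[:, 0] = per * (1 - st.pT1)
        else:
            rng = rng or np.random.default_rng()
            can = rng.binomial(per.astype(np.int64), st.pT1).astype(float)
            st.SD[:, 0] = can
            st.SS[:, 0] = per - can
        return st

    # -- census -----------------------------------------------------------

    def counts(self) -> np.ndarray:
        tot = self.SD.sum(axis=1) + self.SS.sum(axis=1) + self.US.sum(axis=1)
        for L in self.UD:
            tot = tot + L.sum(axis=1)
        return tot

    def total(self) -> float:
        return float(self.counts().sum())

    def dividing_total(self) -> float:
        """Cells still able to divide; a pool with none left cannot be passaged."""
        tot = self.SD.sum()
        if self.foa_on:
            # only post-loss layers within the kill lag will divide again
            tot += sum(L.sum() for L in self.UD[: self.foa_kill_lag])
        else:
            tot += sum(L.sum() for L in self.UD)
        return float(tot)

    def fractions(self) -> np.ndarray:
        c = self.counts()
        tot = c.sum()
        if tot <= 0:
            raise PoolExtinctionError("pool has no cells")
        return c / tot

    def cohort_table(self) -> pd.DataFrame:
        """Cohorts keyed by (barcode_id, replicative_age, silenced) -> count."""
        rows = []
        sil = self.SD + self.SS
        unsil = self.US + sum(self.UD)
        for arr, flag in ((sil, True), (unsil, False)):
            s_idx, a_idx = np.nonzero(arr)
            for s, a in zip(s_idx, a_idx):
                rows.append((self.barcodes[s], int(a), flag, arr[s, a]))
        return pd.DataFrame(rows, columns=["barcode_id", "replicative_age", "silenced", "count"])

    # -- dynamics ---------------------------------------------------------

    def step(self, rng: Optional[np.random.Generator] = None) -> "PoolState":
        if self.mode == "multinomial" and rng is None:
            raise ValueError("multinomial mode requires an rng")
        if self.foa_on:
            # the drug removes reporter-expressing cells: unsilenced senescents
            # and any unsilenced cell past its tolerated post-loss divisions
            self.US[:] = 0.0
            self.UD = self.UD[: self.foa_kill_lag] if self.foa_kill_lag > 0 else []
        if self.mode == "expected":
            self._step_expected()
        else:
            self._step_multinomial(rng)
        self.time_generations += 1
        return self

    def _step_expected(self) -> None:
        SD = self.SD
        daughters = SD.sum(axis=1)
        newSD = np.zeros_like(SD)
        newSD[:, 1:] = SD[:, :-1] * self.tSD
        newUD0 = np.zeros_like(SD)
        newUD0[:, 1:] = SD[:, :-1] * self.tUD
        self.SS[:, 1:] += SD[:, :-1] * self.tSS
        newUS = np.zeros_like(SD)
        newUS[:, 1:] = SD[:, :-1] * self.tUS

        moved_layers = []
        for L in self.UD:
            daughters += L.sum(axis=1)
            moved = np.zeros_like(L)
            moved[:, 1:] = L[:, :-1] * self.rUD
            newUS[:, 1:] += L[:, :-1] * (1 - self.rUD)
            moved_layers.append(moved)

        newSD[:, 0] = daughters * self.pT1
        self.SS[:, 0] += daughters * (1 - self.pT1)
        self.SD = newSD
        if self.foa_on:
            self.US[:] = newUS
            self.UD = [newUD0] + moved_layers
        else:
            self.US += newUS
            base = moved_layers[0] if moved_layers else np.zeros_like(SD)
            self.UD = [base + newUD0]

    def _step_multinomial(self, rng: np.random.Generator) -> None:
        SD = self.SD
        S, A1 = SD.shape
        daughters = SD.sum(axis=1).astype(np.int64)
        newSD = np.zeros_like(SD)
        newUD0 = np.zeros_like(SD)
        newUS = np.zeros_like(SD)
        for s, a in zip(*np.nonzero(SD[:, :-1])):
            n = int(SD[s, a])
            p = np.array([self.tSD[s, a], self.tUD[s, a], self.tSS[s, a], self.tUS[s, a]])
            tot = p.sum()
            if tot <= 0:
                continue
            draw = rng.multinomial(n, p / tot)
            newSD[s, a + 1] += draw[0]
            newUD0[s, a + 1] += draw[1]
            self.SS[s, a + 1] += draw[2]
            newUS[s, a + 1] += draw[3]

        moved_layers = []
        for L in self.UD:
            daughters += L.sum(axis=1).astype(np.int64)
            moved = np.zeros_like(L)
            for s, a in zip(*np.nonzero(L[:, :-1])):
                n = int(L[s, a])
                keep = rng.binomial(n, self.rUD[s, a])
                moved[s, a + 1] += keep
                newUS[s, a + 1] += n - keep
            moved_layers.append(moved)

        can = rng.binomial(daughters, self.pT1).astype(float)
        newSD[:, 0] = can
        self.SS[:, 0] += daughters - can
        self.SD = newSD
        if self.foa_on:
            self.US[:] = newUS
            self.UD = [newUD0] + moved_layers
        else:
            self.US += newUS
            base = moved_layers[0] if moved_layers else np.zeros_like(SD)
            self.UD = [base + newUD0]

    # -- passaging --------------------------------------------------------

    def reseed(self, target_size: float, rng: Optional[np.random.Generator] = None) -> "PoolState":
        total = self.total()
        if total <= 0:
            raise PoolExtinctionError("cannot reseed an empty pool")
        if self.mode == "expected":
            f = target_size / total
            self.SD *= f
            self.SS *= f
            self.US *= f
            self.UD = [L * f for L in self.UD]
        else:
            if rng is None:
                raise ValueError("multinomial reseeding requires an rng")
            arrs = [self.SD, self.SS, self.US] + self.UD
            flat = np.concatenate([a.ravel() for a in arrs])
            draw = rng.multinomial(int(round(target_size)), flat / flat.sum()).astype(float)
            off = 0
            out = []
            for a in arrs:
                n = a.size
                out.append(draw[off : off + n].reshape(a.shape))
                off += n
            self.SD, self.SS, self.US = out[0], out[1], out[2]
            self.UD = out[3:]
        return self


def step_generation(
    state: PoolState, library: Optional[Library] = None, rng: Optional[np.random.Generator] = None
) -> PoolState:
    """Advance the pool by one generation (one synchronous round of divisions)."""
    if library is not None and library.barcode_ids != state.barcodes:
        raise ValueError("library inconsistent with pool state cohort keys")
    return state.step(rng)


def reseed(
    state: PoolState,
    target_size: float,
    mode: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> PoolState:
    """Passage the pool into fresh medium at the target size.

    Expected mode rescales every cohort exactly (relative abundances are
    conserved); multinomial mode draws a bottleneck sample over cohorts, whose
    expectation matches the exact rescale.
    """
    if mode is not None and mode != state.mode:
        raise ValueError(f"reseed mode {mode!r} does not match pool mode {state.mode!r}")
    return state.reseed(target_size, rng)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceTrajectory:
    """Per-strain relative abundances at each sampling day for one condition."""

    condition: str  # plus_foa | minus_foa
    data: pd.DataFrame  # columns: day, condition, barcode_id, rel_abundance

    def __post_init__(self) -> None:
        for day, sub in self.data.groupby("day"):
            s = sub["rel_abundance"].sum()
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                raise ValueError(f"abundances at day {day} sum to {s}, not 1")
            if (sub["rel_abundance"] < 0).any():
                raise ValueError("abundances must be nonnegative")

    @property
    def days(self) -> list[int]:
        return sorted(self.data["day"].unique().tolist())

    def fractions(self, day: int) -> pd.Series:
        sub = self.data[self.data["day"] == day]
        if sub.empty:
            raise KeyError(f"day {day} was not sampled")
        return sub.set_index("barcode_id")["rel_abundance"]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTrajectory":
        df = pd.read_csv(path, sep="\t")
        cond = df["condition"].iloc[0]
        return cls(condition=str(cond), data=df)


def run_screen(
    library: Library,
    schedule: Schedule,
    foa_on: bool,
    mode: str = "expected",
    seed: Optional[int] = None,
    reporter: str = "hml",
) -> AbundanceTrajectory:
    """Run one pooled culture over the schedule and record sampled abundances.

    The pool starts with equal abundance per strain (age 0, silenced),
    advances ``generations_per_day`` synchronous generations per day, is
    passaged back to ``reseed_target_size`` at the reseed interval, and is
    censused at the sampling days.  Expected mode is fully deterministic;
    multinomial mode is deterministic given the seed.
    """
    condition = "plus_foa" if foa_on else "minus_foa"
    rng = np.random.default_rng(seed)
    state = PoolState.initialize(
        library,
        schedule.reseed_target_size,
        foa_on,
        mode=mode,
        reporter=reporter,
        foa_kill_lag=schedule.foa_kill_lag,
        rng=rng,
    )
    rows: list[pd.DataFrame] = []

    def record(day: int) -> None:
        fr = state.fractions()
        rows.append(
            pd.DataFrame(
                {
                    "day": day,
                    "condition": condition,
                    "barcode_id": state.barcodes,
                    "rel_abundance": fr,
                }
            )
        )

    if 0 in schedule.sampling_days:
        record(0)
    for day in range(1, schedule.total_days + 1):
        for _ in range(schedule.generations_per_day):
            state.step(rng)
            if foa_on and state.dividing_total() < (1.0 if mode == "multinomial" else 1e-9):
                raise PoolExtinctionError(
                    f"pool extinct under 5-FOA at day {day} "
                    f"(generation {state.time_generations}): no dividing cells remain"
                )
        if day in schedule.sampling_days:
            record(day)
        if day % schedule.reseed_interval_days == 0 and day < schedule.total_days:
            state.reseed(schedule.reseed_target_size, rng)
    return AbundanceTrajectory(condition=condition, data=pd.concat(rows, ignore_index=True))
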