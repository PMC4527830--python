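"""Replicative- and reproductive-lifespan statistics.

Yeast side: summaries of bud-dissection experiments (mean/median/max
lifespan and the empirical survivor curve) and the Mann-Whitney U procedure
applied, as in the original protocol, to the eight data points flanking the
50% lifespan point of each experiment.  The exact mode enumerates every
rank split — feasible for the 8-vs-8 comparisons this procedure produces —
and the tie-corrected normal approximation with continuity correction covers
larger groups.

Worm side: reproductive-span curves (fraction of adults still producing
viable progeny per day of adulthood, sterile animals excluded) with
matricide handled as right-censoring, and the Mantel-Cox (log-rank) test
between genotypes.  Cessation of reproduction is scored as the last day with
progeny followed by two consecutive progeny-free days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .strains import DissectionSet, ReproSet

__all__ = [
    "RlsSummary",
    "ReproCurve",
    "TestResult",
    "summarize_rls",
    "flank8_select",
    "mann_whitney_u",
    "repro_cessation_day",
    "build_repro_curve",
    "logrank_test",
    "percent_change",
]

EXACT_MAX_N = 10  # auto mode enumerates when both groups are at most this size


@dataclass(frozen=True)
class RlsSummary:
    genotype: str
    n_mothers: int
    mean_lifespan: float
    median_lifespan: float
    max_lifespan: int
    survival_curve: tuple[tuple[int, float], ...]  # (generations, fraction dividing)


@dataclass(frozen=True)
class ReproCurve:
    genotype: str
    fractions: tuple[tuple[int, float], ...]  # (day, fraction reproducing)
    n_included: int
    n_sterile_excluded: int
    n_matricide: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # mann_whitney_exact | mann_whitney_normal | logrank
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


def summarize_rls(data: DissectionSet) -> RlsSummary:
    """Mean, median, max and the empirical survivor curve of a dissection set."""
    v = np.asarray(data.lifespans)
    gmax = int(v.max())
    curve = tuple(
        (g, float(np.mean(v >= g))) for g in range(0, gmax + 2)
    )
    return RlsSummary(
        genotype=data.genotype,
        n_mothers=len(v),
        mean_lifespan=float(v.mean()),
        median_lifespan=float(np.median(v)),
        max_lifespan=gmax,
        survival_curve=curve,
    )


def flank8_select(data: DissectionSet, method: str = "position") -> list[int]:
    """The eight data points flanking the 50% lifespan point.

    ``position`` (default): the 4 sorted values at-or-below the median
    position and the 4 immediately above it — for n mothers these are the
    1-based sorted positions ``ceil(n/2)-3 .. ceil(n/2)+4`` (positions 17-24
    for n = 40).  Ties resolve by sorted index, i.e. toward the median.
    ``value``: the 8 values nearest the median by absolute distance
    (ties toward the center), offered as the alternative reading.
    """
    v = sorted(data.lifespans)
    n = len(v)
    if n < 8:
        raise ValueError("need at least 8 mothers to flank the 50% point")
    if method == "position":
        h = math.ceil(n / 2)
        return v[h - 4 : h + 4]
    if method == "value":
        med = float(np.median(v))
        center = (n - 1) / 2
        order = sorted(range(n), key=lambda i: (abs(v[i] - med), abs(i - center)))
        return sorted(v[i] for i in order[:8])
    raise ValueError("method must be 'position' or 'value'")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for group x: #{x_i > y_j} + half-ties."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2)


@lru_cache(maxsize=32)
def _index_splits(n: int, k: int) -> tuple[tuple[int, ...], ...]:
    return tuple(combinations(range(n), k))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is U for the first group (``U_x + U_y = n1*n2``).
    ``exact`` enumerates all C(n1+n2, n1) rank splits of the pooled sample
    (handles ties via midranks) and returns the two-sided permutation
    p-value; ``normal_approx`` uses the tie-corrected normal approximation
    with continuity correction; ``auto`` picks exact whenever both groups
    have at most 10 points.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    if mode == "auto":
        mode = "exact" if max(n1, n2) <= EXACT_MAX_N else "normal_approx"
    if mode == "exact":
        if math.comb(n1 + n2, n1) > 2_000_000:
            raise ValueError("groups too large for exact enumeration; use normal_approx")
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2
        u_obs = float(ranks[:n1].sum() - offset)
        mid = n1 * n2 / 2
        splits = np.array(_index_splits(n1 + n2, n1))
        u_all = ranks[splits].sum(axis=1) - offset
        p = float(np.mean(np.abs(u_all - mid) >= abs(u_obs - mid) - 1e-9))
        return TestResult(u_obs, p, "mann_whitney_exact", (n1, n2))
    if mode == "normal_approx":
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return TestResult(float(res.statistic), float(res.pvalue), "mann_whitney_normal", (n1, n2))
    raise ValueError("mode must be 'exact', 'normal_approx' or 'auto'")


def repro_cessation_day(daily_progeny: Sequence[int]) -> Optional[int]:
    """Score the end of reproduction from a per-day progeny table (day 1 first).

    Returns the last day ``d`` with progeny such that days ``d+1`` and
    ``d+2`` were observed progeny-free; later progeny resets the rule.
    Returns None (not yet ceased; right-censored) when the two confirming
    empty days were not observed within the table, or when no progeny were
    ever produced.
    """
    v = np.asarray(list(daily_progeny))
    if (v < 0).any():
        raise ValueError("progeny counts must be nonnegative")
    nz = np.nonzero(v)[0]
    if len(nz) == 0:
        return None
    d = int(nz[-1]) + 1  # 1-based day
    return d if len(v) >= d + 2 else None


def build_repro_curve(data: ReproSet, matricide: str = "censor") -> ReproCurve:
    """Fraction of adults generating viable progeny per day of adulthood.

    Sterile worms are excluded from the denominator.  A worm reproduces on
    days 1..c where c is its cessation day.  Matricide removes a
    still-reproducing animal: ``censor`` (default) right-censors it at the
    matricide day via Kaplan-Meier; ``drop`` excludes matricide worms
    entirely, reproducing the plotted-fraction convention.
    """
    if matricide not in ("censor", "drop"):
        raise ValueError("matricide must be 'censor' or 'drop'")
    fertile = data.fertile
    n_sterile = len(data) - len(fertile)
    n_matricide = sum(1 for r in fertile if r.outcome == "matricide")
    if matricide == "drop":
        fertile = tuple(r for r in fertile if r.outcome != "matricide")
    if not fertile:
        raise ValueError("no fertile worms remain")
    durations = np.array([r.last_progeny_day for r in fertile])
    events = np.array([1 if r.outcome == "ceased" else 0 for r in fertile])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    dmax = int(durations.max())
    fractions = tuple(
        # reproducing on day d <=> cessation day >= d <=> survival beyond d-1
        (d, float(kmf.predict(d - 1)))
        for d in range(1, dmax + 2)
    )
    return ReproCurve(
        genotype=data.genotype,
        fractions=fractions,
        n_included=len(fertile),
        n_sterile_excluded=n_sterile,
        n_matricide=n_matricide,
    )


def _surv_inputs(rs: ReproSet) -> tuple[np.ndarray, np.ndarray]:
    fertile = rs.fertile
    durations = np.array([r.last_progeny_day for r in fertile])
    events = np.array([1 if r.outcome == "ceased" else 0 for r in fertile])
    return durations, events


def logrank_test(group_a: ReproSet, group_b: ReproSet) -> TestResult:
    """Mantel-Cox (log-rank) test between two reproductive-span groups.

    Cessation is the event; matricide and end-of-observation are
    right-censoring.  Sterile worms are excluded.  One degree of freedom.
    """
    da, ea = _surv_inputs(group_a)
    db, eb = _surv_inputs(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test needs at least one cessation event")
    res = _ll_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
    return TestResult(
        float(res.test_statistic), float(res.p_value), "logrank", (len(da), len(db))
    )


def percent_change(summary_a: RlsSummary, summary_b: RlsSummary, field: str = "mean") -> float:
    """Percent change of a lifespan summary from a (baseline) to b: 100*(b-a)/a."""
    if field not in ("mean", "median", "max"):
        raise ValueError("field must be 'mean', 'median' or 'max'")
    a = getattr(summary_a, f"{field}_lifespan")
    b = getattr(summary_b, f"{field}_lifespan")
    if a == 0:
        raise ZeroDivisionError("baseline summary value is zero")
    return 100.0 * (b - a) / a
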