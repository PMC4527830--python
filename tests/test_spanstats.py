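"""Lifespan statistics: RLS summaries, flank-8 Mann-Whitney, repro curves, log-rank.

Oracles: the exact Mann-Whitney mode is checked against scipy's exact method
on tie-free data and against a frozen hand-enumerated example; the log-rank
statistic is checked against a hand-worked O-E table (chi-square
1.75^2 / 0.5875 = 5.2127659574) on a six-worm example.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from silencescreen import (
    DissectionSet,
    ReproRecord,
    ReproSet,
    build_repro_curve,
    flank8_select,
    logrank_test,
    mann_whitney_u,
    percent_change,
    repro_cessation_day,
    summarize_rls,
)


def _ds(values, genotype="g"):
    return DissectionSet(genotype=genotype, lifespans=tuple(values))


def _repro(ceased=(), matricide=(), alive=(), sterile=0, genotype="g"):
    recs = (
        [ReproRecord(d, "ceased") for d in ceased]
        + [ReproRecord(d, "matricide") for d in matricide]
        + [ReproRecord(d, "alive_at_end") for d in alive]
        + [ReproRecord(None, None, sterile=True)] * sterile
    )
    return ReproSet(genotype=genotype, records=tuple(recs))


class TestSummarizeRls:
    def test_constant_data(self):
        s = summarize_rls(_ds([30, 30, 30]))
        assert (s.mean_lifespan, s.median_lifespan, s.max_lifespan) == (30, 30, 30)

    def test_hand_computed_summary(self):
        s = summarize_rls(_ds([10, 20, 30, 40]))
        assert s.mean_lifespan == 25 and s.median_lifespan == 25 and s.max_lifespan == 40

    def test_survivor_curve_shape(self):
        s = summarize_rls(_ds([1, 2, 2, 4]))
        curve = dict(s.survival_curve)
        assert curve[0] == 1.0
        assert curve[2] == 0.75 and curve[3] == 0.25 and curve[5] == 0.0
        fractions = [f for _, f in s.survival_curve]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestFlank8:
    def test_n8_returns_everything(self):
        assert flank8_select(_ds(range(1, 9))) == list(range(1, 9))

    def test_n40_selects_positions_17_to_24(self):
        values = list(range(100, 140))  # sorted, distinct
        assert flank8_select(_ds(values)) == values[16:24]

    def test_constant_data(self):
        assert flank8_select(_ds([7] * 12)) == [7] * 8

    def test_value_method_picks_nearest_to_median(self):
        # median is 13: the value-nearest reading keeps the low point at
        # distance 12 and drops the far outlier at distance 87, whereas the
        # positional window keeps the outlier
        vals = [1, 10, 11, 12, 13, 14, 15, 16, 100]
        assert flank8_select(_ds(vals), method="value") == [1, 10, 11, 12, 13, 14, 15, 16]
        assert flank8_select(_ds(vals), method="position") == [10, 11, 12, 13, 14, 15, 16, 100]

    def test_small_sets_rejected(self):
        with pytest.raises(ValueError):
            flank8_select(_ds([1] * 7))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 60), min_size=8, max_size=45))
    def test_selection_is_multiset_subset_containing_median_position(self, values):
        from collections import Counter

        sel = flank8_select(_ds(values))
        assert len(sel) == 8
        assert not Counter(sel) - Counter(values)
        v = sorted(values)
        assert v[math.ceil(len(v) / 2) - 1] in sel  # the 50% point itself


class TestMannWhitney:
    def test_identical_groups(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4], mode="exact")
        assert res.statistic == 8.0  # n1*n2/2
        assert res.p_value == 1.0
        assert res.method == "mann_whitney_exact"

    def test_complete_separation_hand_enumeration(self):
        # all C(8,4)=70 rank splits; only U=0 and U=16 are as extreme
        res = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 70)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_scipy_enumeration(self, seed):
        pool = np.random.default_rng(seed).permutation(100).astype(float)
        x, y = pool[:6], pool[6:14]  # tie-free by construction
        ours = mann_whitney_u(x, y, mode="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.statistic == ref.statistic
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_normal_approx_close_to_exact_for_8v8(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.8, 1, 8)
        exact = mann_whitney_u(x, y, mode="exact")
        approx = mann_whitney_u(x, y, mode="normal_approx")
        assert approx.method == "mann_whitney_normal"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_auto_mode_switches_on_group_size(self):
        small = mann_whitney_u(range(8), range(4, 12), mode="auto")
        big = mann_whitney_u(range(30), range(5, 35), mode="auto")
        assert small.method == "mann_whitney_exact"
        assert big.method == "mann_whitney_normal"

    def test_u_complement_identity(self):
        x, y = [3.0, 9.0, 1.0, 7.0], [2.0, 8.0, 8.0]
        ux = mann_whitney_u(x, y, mode="exact").statistic
        uy = mann_whitney_u(y, x, mode="exact").statistic
        assert ux + uy == len(x) * len(y)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCessationDay:
    @pytest.mark.parametrize(
        "progeny, expected",
        [
            ([5, 8, 6, 0, 0], 3),
            ([5, 0, 0, 2, 0, 0], 4),  # later progeny resets the rule
            ([5, 8, 6, 0], None),  # only one empty day observed
            ([0, 0, 0], None),
            ([4, 0, 0], 1),
        ],
    )
    def test_two_empty_day_rule(self, progeny, expected):
        assert repro_cessation_day(progeny) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            repro_cessation_day([3, -1, 0])


class TestReproCurve:
    def test_all_cease_same_day(self):
        curve = build_repro_curve(_repro(ceased=[4, 4, 4]))
        frac = dict(curve.fractions)
        assert frac[1] == frac[4] == 1.0
        assert frac[5] == 0.0

    def test_half_cease_day2_half_day6(self):
        curve = build_repro_curve(_repro(ceased=[2, 2, 6, 6]))
        frac = dict(curve.fractions)
        assert frac[2] == 1.0
        for d in (3, 4, 5, 6):
            assert frac[d] == pytest.approx(0.5)
        assert frac[7] == 0.0

    def test_sterile_excluded_without_changing_fractions(self):
        with_sterile = build_repro_curve(_repro(ceased=[2, 3, 5], sterile=4))
        without = build_repro_curve(_repro(ceased=[2, 3, 5]))
        assert with_sterile.n_included == 3 and with_sterile.n_sterile_excluded == 4
        assert with_sterile.fractions == without.fractions

    def test_matricide_censor_vs_drop(self):
        rs = _repro(ceased=[2, 2, 6, 6], matricide=[4])
        censored = build_repro_curve(rs, matricide="censor")
        dropped = build_repro_curve(rs, matricide="drop")
        assert censored.n_matricide == 1
        assert dropped.n_included == 4
        # the censored worm keeps the day-3..4 at-risk fraction higher
        assert dict(censored.fractions)[3] > dict(dropped.fractions)[3]

    def test_monotone_nonincreasing(self):
        rs = _repro(ceased=[1, 3, 3, 7, 2], matricide=[5, 2], alive=[8])
        fr = [f for _, f in build_repro_curve(rs).fractions]
        assert all(a >= b - 1e-12 for a, b in zip(fr, fr[1:]))

    def test_no_usable_worms_rejected(self):
        with pytest.raises(ValueError):
            build_repro_curve(_repro(sterile=3), matricide="censor")
        with pytest.raises(ValueError):
            build_repro_curve(_repro(matricide=[2], sterile=1), matricide="drop")


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        a = _repro(ceased=[2, 3, 5])
        res = logrank_test(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "logrank"

    def test_hand_worked_oe_table(self):
        # A ceases {2,2,3}, B ceases {5,6,6}: O_A=3, E_A=1.25, Var=0.5875
        a = _repro(ceased=[2, 2, 3], genotype="A")
        b = _repro(ceased=[5, 6, 6], genotype="B")
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(1.75**2 / 0.5875, rel=1e-9)
        assert res.p_value == pytest.approx(sps.chi2.sf(1.75**2 / 0.5875, 1), rel=1e-9)

    def test_rank_invariance_under_time_doubling(self):
        a = _repro(ceased=[2, 3, 5, 7], matricide=[4])
        b = _repro(ceased=[1, 2, 2, 6])
        a2 = _repro(ceased=[4, 6, 10, 14], matricide=[8])
        b2 = _repro(ceased=[2, 4, 4, 12])
        r1, r2 = logrank_test(a, b), logrank_test(a2, b2)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_matricide_worm_stays_at_risk_until_removal(self):
        # identical cessation events, but one matricide worm in B inflates
        # B's at-risk set at every event time: the statistic leaves zero
        a = _repro(ceased=[2, 3, 5], genotype="A")
        b = _repro(ceased=[2, 3, 5], matricide=[6], genotype="B")
        res = logrank_test(a, b)
        assert res.statistic > 0.1
        assert logrank_test(a, a).statistic == pytest.approx(0.0, abs=1e-12)

    def test_no_events_rejected(self):
        a = _repro(matricide=[2, 3])
        with pytest.raises(ValueError):
            logrank_test(a, a)


class TestPercentChange:
    def test_published_reporting_style(self):
        a = summarize_rls(_ds([10, 10]))
        b = summarize_rls(_ds([14, 14]))
        assert percent_change(a, b, "median") == pytest.approx(40.0)

    def test_mean_extension_between_published_means(self):
        a = summarize_rls(_ds([17, 18]))  # mean 17.5
        b = summarize_rls(_ds([27, 28]))  # mean 27.5
        assert percent_change(a, b, "mean") == pytest.approx(100 * 10 / 17.5)

    def test_equal_summaries_and_zero_baseline(self):
        a = summarize_rls(_ds([5, 5]))
        assert percent_change(a, a, "mean") == 0.0
        z = summarize_rls(_ds([0, 0]))
        with pytest.raises(ZeroDivisionError):
            percent_change(z, a, "max")
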