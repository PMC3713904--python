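"""Concordance, Spearman, Bland-Altman and the two comparison batteries."""

import numpy as np
import pandas as pd
import pytest

import actipair as ap
from actipair.agreement import ParticipantMinutes


def brute_force_ccc(x, y):
    """Direct evaluation of 2*sxy / (sxx + syy + (mx-my)^2), n-denominator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x) / n
    syy = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * sxy / (sxx + syy + (mx - my) ** 2)


def hand_spearman(x, y):
    """Rank both sequences with average ranks for ties, then Pearson on ranks."""

    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return (rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum())


class TestCCC:
    def test_identity_is_perfect_concordance(self):
        x = np.arange(10.0)
        assert ap.ccc(x, x).ccc == pytest.approx(1.0)

    def test_location_shift_penalized_below_pearson(self):
        x = np.arange(10.0)
        res = ap.ccc(x, x + 3.0)
        assert res.ccc < 1.0  # Pearson correlation is exactly 1 here

    def test_ten_pair_table_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, 10)
        y = 0.8 * x + rng.normal(0, 0.5, 10) + 0.3
        assert ap.ccc(x, y).ccc == pytest.approx(brute_force_ccc(x, y), abs=1e-12)

    def test_bounded_by_pearson_magnitude(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0.2, 1.5, 30)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ap.ccc(x, y).ccc) <= abs(r) + 1e-12

    def test_equals_pearson_when_means_and_variances_match(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 500)
        y = x[::-1].copy()  # same empirical mean and variance
        r = np.corrcoef(x, y)[0, 1]
        assert ap.ccc(x, y).ccc == pytest.approx(r, abs=1e-12)

    def test_both_constant_is_undefined(self):
        with pytest.raises(ap.UndefinedStatisticError):
            ap.ccc(np.ones(5), np.ones(5))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(12)
        x = rng.normal(5, 2, 100)
        y = x + rng.normal(0, 1, 100)
        res = ap.ccc(x, y)
        assert res.ci_low < res.ccc < res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_variance_ratio_interpretation_on_two_level_data(self):
        # subject means sigma_b^2 apart, two methods each adding sigma_m^2:
        # CCC of subject means ~ sigma_b^2 / (sigma_b^2 + sigma_m^2)
        rng = np.random.default_rng(13)
        sigma_b, sigma_m = 2.0, 1.0
        subjects = rng.normal(0, sigma_b, 4000)
        x = subjects + rng.normal(0, sigma_m, 4000)
        y = subjects + rng.normal(0, sigma_m, 4000)
        expected = sigma_b**2 / (sigma_b**2 + sigma_m**2)
        assert ap.ccc(x, y).ccc == pytest.approx(expected, abs=0.03)

    def test_invariant_to_common_permutation(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 0.3, 50)
        perm = rng.permutation(50)
        assert ap.ccc(x, y).ccc == pytest.approx(ap.ccc(x[perm], y[perm]).ccc, abs=1e-14)


class TestSpearman:
    def test_monotone_sequences_score_one(self):
        x = np.arange(20.0)
        assert ap.spearman_with_ci(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(15)
        res = ap.spearman_with_ci(rng.uniform(size=10000), rng.uniform(size=10000))
        assert abs(res.rho) < 0.05

    def test_eight_pair_table_with_tie_matches_hand_ranking(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 9.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 8.0, 7.0]
        res = ap.spearman_with_ci(x, y)
        assert res.rho == pytest.approx(hand_spearman(x, y), abs=1e-12)

    def test_constant_input_is_undefined(self):
        with pytest.raises(ap.UndefinedStatisticError):
            ap.spearman_with_ci(np.ones(10), np.arange(10.0))

    def test_fisher_ci_narrows_with_n(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=2000)
        small = ap.spearman_with_ci(x[:50], (x + rng.normal(0, 1, 2000))[:50])
        big = ap.spearman_with_ci(x, x + rng.normal(0, 1, 2000))
        assert (big.ci_high - big.ci_low) < (small.ci_high - small.ci_low)


class TestBlandAltman:
    def test_identical_methods_have_zero_bias(self):
        x = np.arange(10.0)
        res = ap.bland_altman(x, x)
        assert res.mean_diff == 0.0
        assert res.bias_slope == 0.0
        assert not res.bias_significant

    def test_constant_difference_gives_degenerate_limits(self):
        x = np.arange(10.0)
        res = ap.bland_altman(x + 2.5, x)
        assert res.mean_diff == pytest.approx(2.5)
        assert res.loa_low == pytest.approx(2.5)
        assert res.loa_high == pytest.approx(2.5)

    def test_proportional_bias_detected_at_n_500(self):
        rng = np.random.default_rng(17)
        m = rng.uniform(10, 50, 500)
        d = 0.5 * m + rng.normal(0, 2, 500)
        x = m + d / 2
        y = m - d / 2
        res = ap.bland_altman(x, y)
        assert res.bias_slope_ci[0] <= 0.5 <= res.bias_slope_ci[1]
        assert res.bias_significant

    def test_limits_contain_about_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(18)
        y = rng.uniform(0, 10, 1000)
        x = y + rng.normal(0.5, 1.0, 1000)
        res = ap.bland_altman(x, y)
        d = x - y
        frac = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        # binomial 99.9% band around 0.95 at n=1000 is ~ +/- 0.022
        assert 0.925 <= frac <= 0.975

    def test_plot_table_carries_means_and_diffs(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([0.0, 2.0, 2.0])
        res = ap.bland_altman(x, y)
        assert list(res.table["mean"]) == [0.5, 2.0, 3.0]
        assert list(res.table["diff"]) == [1.0, 0.0, 2.0]
        assert set(res.annotations()) >= {"mean_diff", "loa_low", "loa_high", "bias_slope"}

    def test_insufficient_pairs_is_an_error(self):
        with pytest.raises(ap.UndefinedStatisticError):
            ap.bland_altman([1.0, 2.0], [1.0, 2.0])


def participant(pid, ref_mets, phone_mets, slope=520.98, intercept=-186.54):
    ref_mets = np.asarray(ref_mets, float)
    phone_mets = np.asarray(phone_mets, float)
    g = np.maximum(0.0, (phone_mets - 1.2907087) / 0.4141791)
    counts = np.maximum(0.0, (ref_mets - 1.439008) / 0.000795)
    return ParticipantMinutes(pid, g, counts, phone_mets, ref_mets)


class TestCompareMinutes:
    def test_linear_transform_gives_perfect_vt_agreement(self):
        rng = np.random.default_rng(19)
        parts = []
        for i in range(6):
            mets = rng.uniform(1.5, 8, 400)
            parts.append(participant(f"p{i}", mets, mets))
        cmp = ap.compare_minutes(parts)
        assert cmp.vt.adjusted_r2 == pytest.approx(1.0)
        assert cmp.active_pct.ccc.ccc == pytest.approx(1.0)
        assert cmp.mean_met.bland_altman.mean_diff == pytest.approx(0.0, abs=1e-12)
        assert cmp.excluded == []

    def test_zero_joint_minutes_participant_excluded_with_reason(self):
        good = participant("ok", [2.0] * 100 + [4.0] * 50, [2.0] * 100 + [4.1] * 50)
        empty = ParticipantMinutes("empty", np.array([]), np.array([]), np.array([]), np.array([]))
        cmp = ap.compare_minutes([good, empty])
        assert cmp.excluded == [("empty", "no_joint_minutes")]

    def test_vigorous_only_underestimation_flags_vigorous_bias(self):
        # phone halves vigorous duration, in proportion to how much vigorous
        # activity the participant does; light duration agrees exactly
        rng = np.random.default_rng(20)
        parts = []
        for i in range(20):
            v = 10 + 4 * i  # vigorous minutes grow across participants
            n = 600
            ref = np.concatenate([np.full(v, 7.0), np.full(n - v, 2.0)])
            phone = ref.copy()
            phone[: v // 2] = 5.5  # half the vigorous minutes read as moderate
            parts.append(participant(f"p{i}", ref, phone))
        cmp = ap.compare_minutes(parts)
        assert cmp.class_durations["vigorous"].bland_altman.bias_significant
        assert not cmp.class_durations["light"].bland_altman.bias_significant

    def test_within_class_table_uses_reference_classification(self):
        ref = [2.0] * 50 + [4.0] * 30 + [7.0] * 20
        phone = [2.0] * 50 + [4.0] * 30 + [5.9] * 20  # phone underestimates vigorous
        cmp = ap.compare_minutes([participant("p", ref, phone)])
        tab = cmp.class_intensity.table
        assert tab.loc["vigorous", "n"] == 20  # minutes assigned by the reference
        assert tab.loc["vigorous", "phone_mean"] < tab.loc["vigorous", "ref_mean"]
        assert int(tab["n"].sum()) == 100  # all non-sedentary joint minutes

    def test_statistics_invariant_to_participant_order(self):
        rng = np.random.default_rng(21)
        parts = [
            participant(f"p{i}", rng.uniform(1, 8, 300), rng.uniform(1, 8, 300))
            for i in range(5)
        ]
        a = ap.compare_minutes(parts)
        b = ap.compare_minutes(parts[::-1])
        assert a.vt.spearman.rho == pytest.approx(b.vt.spearman.rho)
        assert a.active_pct.ccc.ccc == pytest.approx(b.active_pct.ccc.ccc)


def day_table(rows):
    idx = pd.MultiIndex.from_tuples(
        [(r["participant"], pd.Timestamp(r["day"])) for r in rows],
        names=["participant", "day"],
    )
    cols = ["light_minutes", "moderate_minutes", "vigorous_minutes",
            "active_minutes", "mean_met", "valid"]
    return pd.DataFrame([{c: r[c] for c in cols} for r in rows], index=idx)


class TestCompareDays:
    def _rows(self, light, valid=True):
        return [
            {
                "participant": "p1",
                "day": f"2013-03-{4 + i:02d}",
                "light_minutes": li,
                "moderate_minutes": 40.0 + i,
                "vigorous_minutes": 10.0,
                "active_minutes": li + 50.0 + i,
                "mean_met": 2.0 + 0.1 * i,
                "valid": valid,
            }
            for i, li in enumerate(light)
        ]

    def test_identical_day_summaries_agree_perfectly(self):
        rows = self._rows([100.0, 120.0, 140.0, 160.0])
        cmp = ap.compare_days(day_table(rows), day_table(rows))
        assert not cmp.empty
        for rep in cmp.reports.values():
            assert rep.bland_altman.mean_diff == pytest.approx(0.0)

    def test_only_days_valid_on_both_devices_enter(self):
        phone = day_table(self._rows([100.0, 120.0, 140.0, 160.0]))
        ref = day_table(self._rows([100.0, 120.0, 140.0, 160.0]))
        phone.loc[("p1", pd.Timestamp("2013-03-04")), "valid"] = False
        cmp = ap.compare_days(phone, ref)
        assert cmp.n_days == 3

    def test_no_coinciding_valid_days_yields_empty_flag(self):
        phone = day_table(self._rows([100.0, 120.0, 140.0], valid=False))
        ref = day_table(self._rows([100.0, 120.0, 140.0]))
        cmp = ap.compare_days(phone, ref)
        assert cmp.empty
        assert cmp.reports == {}
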