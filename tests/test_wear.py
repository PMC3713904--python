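"""Nonwear detection, usability bookkeeping and the Kruskal-Wallis comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import actipair as ap
from actipair.epochs import UNIT_COUNTS
from actipair.wear import NONWEAR, NOT_RECORDED, WORN

from conftest import minute_series


def counts_series(values):
    return minute_series(values, unit=UNIT_COUNTS)


class TestDetectNonwear:
    @pytest.mark.parametrize("run,expected_episodes", [(39, 0), (40, 1), (41, 1)])
    def test_forty_minute_rule_boundary(self, run, expected_episodes):
        vals = [500.0] * 10 + [0.0] * run + [500.0] * 10
        mask = ap.detect_nonwear(counts_series(vals))
        episodes = mask.nonwear_episodes()
        assert len(episodes) == expected_episodes
        if episodes:
            assert episodes[0].length == run

    def test_single_active_minute_splits_runs(self):
        # two 39-min near-zero runs separated by one active minute: neither
        # reaches 40 consecutive minutes, so no nonwear at all
        vals = [0.0] * 39 + [300.0] + [0.0] * 39
        mask = ap.detect_nonwear(counts_series(vals))
        assert len(mask.nonwear_episodes()) == 0
        # but two 45-min runs with a break remain two distinct episodes
        vals = [0.0] * 45 + [300.0] + [0.0] * 45
        mask = ap.detect_nonwear(counts_series(vals))
        assert [e.length for e in mask.nonwear_episodes()] == [45, 45]

    def test_g_series_below_threshold_is_nonwear(self):
        mask = ap.detect_nonwear(minute_series([0.29] * 60))
        assert [e.length for e in mask.nonwear_episodes()] == [60]

    def test_g_value_at_threshold_is_worn(self):
        mask = ap.detect_nonwear(minute_series([0.3] * 60))
        assert len(mask.nonwear_episodes()) == 0

    def test_zero_counts_exactly_are_nonwear_but_one_count_is_not(self):
        mask = ap.detect_nonwear(counts_series([0.0] * 60))
        assert mask.minutes(NONWEAR) == 60
        mask = ap.detect_nonwear(counts_series([1.0] * 60))
        assert mask.minutes(NONWEAR) == 0

    def test_missing_minutes_break_runs_and_are_not_recorded(self):
        vals = [0.0] * 30 + [np.nan] * 5 + [0.0] * 30
        mask = ap.detect_nonwear(counts_series(vals))
        assert len(mask.nonwear_episodes()) == 0
        assert mask.minutes(NOT_RECORDED) == 5

    def test_g_threshold_on_counts_series_is_configuration_error(self):
        with pytest.raises(ap.ConfigurationError):
            ap.detect_nonwear(counts_series([0.0] * 60), zero_threshold=0.3)

    @given(st.lists(st.sampled_from([0.0, 0.1, 1.5, float("nan")]), min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_states_partition_all_minutes(self, values):
        series = minute_series(values)
        mask = ap.detect_nonwear(series)
        assert mask.minutes(WORN) + mask.minutes(NONWEAR) + mask.minutes(NOT_RECORDED) == len(series)
        assert sum(e.length for e in mask.episodes) == len(series)
        # episodes are maximal: no two adjacent episodes share a state
        states = [e.state for e in mask.episodes]
        assert all(a != b for a, b in zip(states, states[1:]))
        # every nonwear episode respects the minimum run
        assert all(e.length >= 40 for e in mask.nonwear_episodes())

    @given(
        st.lists(st.sampled_from([0.0, 0.1, 1.5]), min_size=1, max_size=200),
        st.integers(min_value=10, max_value=60),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_lowering_min_run_never_decreases_nonwear(self, values, min_run):
        series = minute_series(values)
        high = ap.detect_nonwear(series, min_run=min_run)
        low = ap.detect_nonwear(series, min_run=max(min_run - 5, 1))
        assert low.minutes(NONWEAR) >= high.minutes(NONWEAR)

    def test_invariant_to_appending_not_recorded_minutes(self):
        vals = [500.0] * 10 + [0.0] * 45 + [500.0] * 10
        base = ap.detect_nonwear(counts_series(vals))
        extended = ap.detect_nonwear(counts_series(vals + [np.nan] * 20))
        n = len(vals)
        assert list(extended.states.iloc[:n]) == list(base.states)
        assert list(extended.states.iloc[n:]) == [NOT_RECORDED] * 20


def full_day(worn_minutes, total=1440, level=1.0):
    """One day: `worn_minutes` of activity then zeros (nonwear), NaN padding."""
    vals = [level] * worn_minutes + [0.0] * (total - worn_minutes)
    return vals


class TestUsabilitySummary:
    def test_five_full_days_worn_is_valid_assessment(self):
        vals = [1.0] * (5 * 1440)
        series = counts_series(vals)
        mask = ap.detect_nonwear(series)
        summ = ap.usability_summary(series, mask, "p1")
        assert summ.days_recorded == 5
        assert summ.n_valid_days == 5
        assert summ.valid_assessment
        assert summ.pct_worn_of_recorded == pytest.approx(100.0)

    def test_two_eleven_hour_days_is_not_valid_assessment(self):
        day = [1.0] * (11 * 60) + [np.nan] * (1440 - 11 * 60)
        series = counts_series(day * 2)
        mask = ap.detect_nonwear(series)
        summ = ap.usability_summary(series, mask, "p1")
        assert summ.days_recorded == 2
        assert summ.n_valid_days == 2
        assert not summ.valid_assessment

    def test_worn_never_exceeds_recorded(self):
        series = counts_series(full_day(600) * 3)
        mask = ap.detect_nonwear(series)
        summ = ap.usability_summary(series, mask)
        assert summ.worn_minutes <= summ.recorded_minutes
        assert summ.pct_worn_of_recorded == pytest.approx(
            100.0 * summ.worn_minutes / summ.recorded_minutes
        )

    def test_valid_day_basis_recorded_counts_recording_not_wear(self):
        # 24 h recorded but only 8 h worn: invalid on the wear basis,
        # valid on the recorded basis
        series = counts_series(full_day(8 * 60) * 3)
        mask = ap.detect_nonwear(series)
        worn = ap.usability_summary(series, mask, valid_day_basis="worn")
        rec = ap.usability_summary(series, mask, valid_day_basis="recorded")
        assert worn.n_valid_days == 0
        assert rec.n_valid_days == 3

    def test_empty_series_yields_zero_summary(self):
        series = counts_series([np.nan, np.nan])
        mask = ap.detect_nonwear(series)
        summ = ap.usability_summary(series, mask)
        assert summ.days_recorded == 0
        assert summ.recorded_minutes == 0
        assert not summ.valid_assessment


def summaries_with(metric_values, metric="n_valid_days"):
    out = []
    for v in metric_values:
        s = ap.UsabilitySummary("p", "d", 0, 0, 0, 0.0, 0.0, 0.0, 0, False)
        setattr(s, metric, v)
        out.append(s)
    return out


class TestCompareUsability:
    def test_identical_groups_give_h_zero_p_one(self):
        g = summaries_with([3, 3, 3])
        table = ap.compare_usability(g, g)
        assert (table["H"] == 0).all()
        assert (table["p_value"] == 1).all()

    def test_separated_groups_match_hand_computed_rank_statistic(self):
        # groups {1,2,3} and {10,11,12}: ranks 1-3 vs 4-6, no ties;
        # H = 12/(6*7) * [3*(2-3.5)^2 + 3*(5-3.5)^2] = 27/7
        a = summaries_with([1, 2, 3])
        b = summaries_with([10, 11, 12])
        table = ap.compare_usability(a, b)
        assert table.loc["n_valid_days", "H"] == pytest.approx(27 / 7, abs=1e-12)

    def test_three_groups_supported_and_match_reference_implementation(self):
        groups = [summaries_with(v) for v in ([1, 5, 3], [2, 8, 6], [9, 4, 7])]
        table = ap.compare_usability(*groups, labels=("a", "b", "c"))
        h_ref, p_ref = stats.kruskal([1, 5, 3], [2, 8, 6], [9, 4, 7])
        assert table.loc["n_valid_days", "H"] == pytest.approx(h_ref)
        assert table.loc["n_valid_days", "p_value"] == pytest.approx(p_ref)

    def test_reports_per_group_median_and_iqr(self):
        a = summaries_with([1, 2, 3, 4])
        b = summaries_with([10, 20, 30, 40])
        table = ap.compare_usability(a, b, labels=("x", "y"))
        assert table.loc["n_valid_days", "x_median"] == 2.5
        assert table.loc["n_valid_days", "y_median"] == 25.0
        assert table.loc["n_valid_days", "y_iqr_low"] <= 25 <= table.loc["n_valid_days", "y_iqr_high"]
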