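"""Event definitions: inactivity, window segmentation, gaps, resumption."""

import numpy as np
import pytest

from bpdropout import (
    ConfigError,
    detect_gaps,
    detect_resumption,
    inactive_at,
    label_cohort,
    label_window,
    segment_windows,
)
from bpdropout.labeling import InsufficientFollowup, ObservationWindow, first_inactive_onset

from ._oracles import brute_gaps, brute_inactive, brute_resumption, random_series_pattern
from .conftest import make_series


class TestInactiveAt:
    def test_daily_measurer_never_inactive(self):
        s = make_series(range(0, 100), cutoff=99)
        assert not any(inactive_at(s, t) for t in range(0, 100))

    def test_28_day_boundary_after_single_measurement(self):
        s = make_series([0], cutoff=60)
        assert not inactive_at(s, 27)
        assert inactive_at(s, 28)

    def test_interval_is_trailing_and_closed(self):
        s = make_series([0, 30], cutoff=40)
        assert inactive_at(s, 29)  # [2, 29] holds nothing
        assert not inactive_at(s, 30)  # day 30 measured

    def test_beyond_cutoff_signals_insufficient_followup(self):
        s = make_series([0], cutoff=10)
        with pytest.raises(InsufficientFollowup):
            inactive_at(s, 11)


class TestSegmentWindows:
    def test_exactly_one_window_for_14_day_span(self):
        s = make_series(range(5, 19), cutoff=18)
        w = segment_windows(s)
        assert [(x.start_day, x.end_day) for x in w] == [(5, 18)]

    def test_partial_trailing_segment_discarded(self):
        s = make_series([1, 30], cutoff=30)  # 30-day span from day 1
        w = segment_windows(s)
        assert [(x.start_day, x.end_day) for x in w] == [(1, 14), (15, 28)]

    def test_hundred_day_span_gives_seven_windows(self):
        s = make_series([1, 100], cutoff=100)
        w = segment_windows(s)
        assert [x.start_day for x in w] == [1 + 14 * i for i in range(7)]
        assert all(x.end_day - x.start_day == 13 for x in w)

    def test_windows_partition_prefix_of_followup(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            days, cutoff = random_series_pattern(rng)
            s = make_series(days, cutoff)
            w = segment_windows(s)
            covered = sorted(d for x in w for d in range(x.start_day, x.end_day + 1))
            k = len(w)
            assert covered == list(range(s.first_day, s.first_day + 14 * k))


class TestLabelWindow:
    def test_daily_measurer_labeled_zero(self):
        s = make_series(range(0, 120), cutoff=119)
        w = segment_windows(s)[0]
        assert label_window(s, w, 28) == 0

    def test_silent_user_labeled_one_for_every_horizon(self):
        s = make_series(range(0, 14), cutoff=200)
        w = segment_windows(s)[0]
        assert all(label_window(s, w, X) == 1 for X in range(28, 92, 7))

    def test_single_post_window_measurement_flips_with_horizon(self):
        # window [0, 13], one later reading at day 43 (= end + 30)
        s = make_series(list(range(0, 14)) + [43], cutoff=200)
        w = segment_windows(s)[0]
        assert label_window(s, w, 28) == 1  # (14..41] has a 28-day tail clear of 43
        assert label_window(s, w, 35) == 0  # interval [21, 48] contains 43

    def test_undefined_when_followup_too_short(self):
        s = make_series(range(0, 14), cutoff=30)
        w = segment_windows(s)[0]
        assert label_window(s, w, 28) is None

    def test_off_grid_horizon_rejected(self):
        s = make_series(range(0, 14), cutoff=200)
        w = segment_windows(s)[0]
        with pytest.raises(ConfigError):
            label_window(s, w, 30)


class TestDetectGaps:
    def test_daily_measurer_has_no_gaps(self):
        s = make_series(range(0, 50), cutoff=49)
        assert detect_gaps(s) == []

    def test_internal_gap_run_length(self):
        s = make_series([1, 2, 10], cutoff=10)
        (g,) = detect_gaps(s)
        assert (g.gap_start, g.gap_length) == (3, 7)

    def test_trailing_gap_counted_to_cutoff(self):
        s = make_series([1], cutoff=200)
        (g,) = detect_gaps(s)
        assert (g.gap_start, g.gap_length) == (2, 199)
        assert g.followup_days == 199

    def test_resumption_status_undefined_without_180_day_followup(self):
        s = make_series([1, 10], cutoff=100)
        statuses = [g.resumed_within_180 for g in detect_gaps(s)]
        assert statuses == [None, None]


class TestDetectResumption:
    def test_daily_measurer_resumes_immediately(self):
        s = make_series(range(0, 60), cutoff=59)
        assert detect_resumption(s, 5) == 6

    def test_single_isolated_measurement_is_not_resumption(self):
        s = make_series([0, 40], cutoff=200)
        assert detect_resumption(s, 10) is None

    def test_weekly_for_four_weeks_qualifies(self):
        s = make_series([0, 40, 47, 54, 61], cutoff=80)
        assert detect_resumption(s, 10) == 40

    def test_unconfirmable_near_cutoff_yields_none(self):
        s = make_series([0, 40, 47, 54, 61], cutoff=66)  # 40 + 27 > 66
        assert detect_resumption(s, 10) is None


class TestOracleEquivalence:
    """Brute-force day-scan agreement on random short series."""

    def test_all_event_operations_match_brute_force(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            days, cutoff = random_series_pattern(rng)
            s = make_series(days, cutoff)
            mset = set(days)
            first = min(days)
            for t in range(0, cutoff + 1, 3):
                assert inactive_at(s, t) == brute_inactive(mset, t, first)
            got = [(g.gap_start, g.gap_length) for g in detect_gaps(s)]
            assert got == brute_gaps(days, cutoff)
            for a in (first, first + 7, cutoff // 2):
                assert detect_resumption(s, a) == brute_resumption(days, a, cutoff)
            for w in segment_windows(s)[:3]:
                for X in (28, 56, 91):
                    t = w.end_day + X
                    expect = (
                        None if t > cutoff else int(brute_inactive(mset, t, first))
                    )
                    assert label_window(s, w, X) == expect

    def test_positive_label_implies_covering_gap_episode(self):
        rng = np.random.default_rng(321)
        checked = 0
        for _ in range(200):
            days, cutoff = random_series_pattern(rng)
            s = make_series(days, cutoff)
            gaps = detect_gaps(s)
            for w in segment_windows(s):
                for X in (28, 56):
                    if label_window(s, w, X) == 1:
                        t = w.end_day + X
                        assert any(
                            g.gap_start <= t - 27 and g.gap_start + g.gap_length - 1 >= t
                            for g in gaps
                        )
                        checked += 1
        assert checked >= 5  # sparse series with enough follow-up are rare


class TestFirstInactiveOnset:
    def test_onset_is_28th_day_of_first_long_gap(self):
        s = make_series([0, 1, 2, 60], cutoff=200)
        # gap starts day 3; the 28-day rule first fires at day 30
        assert first_inactive_onset(s) == 30
        assert inactive_at(s, 30) and not inactive_at(s, 29)

    def test_no_onset_for_steady_measurer(self):
        s = make_series(range(0, 100, 5), cutoff=104)
        assert first_inactive_onset(s) is None


def test_label_cohort_row_per_window(study_series, study_windows):
    some_uid = next(iter(study_series))
    n_windows = len(segment_windows(study_series[some_uid]))
    assert (study_windows["user_id"] == some_uid).sum() == n_windows
    # labels defined only where follow-up suffices; undefined coded -1
    for X in (28, 56, 84):
        undef = study_windows.loc[~study_windows[f"defined_{X}"], f"y_{X}"]
        assert (undef == -1).all()


def test_window_type_enforces_14_days():
    with pytest.raises(ValueError):
        ObservationWindow("u", 0, 14)
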