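from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dna_monitor.event_io import ActivityInterval, NOON_ANCHOR
from dna_monitor.sleep import (
    SdpWeights,
    SleepSession,
    build_sleep_reference,
    compute_sci,
    compute_sdd,
    compute_sdp,
    compute_sii,
    compute_sod,
    extract_sleep_sessions,
    flag_sleep_days,
    score_sleep_sessions,
)
from dna_monitor.wadi import ThresholdConfig

D0 = date(2016, 12, 23)


def _iv(activity, start, end, night=D0):
    return ActivityInterval(activity, start, end, night)


class TestExtractSleepSessions:
    def test_uninterrupted_night(self):
        intervals = [
            _iv("Sleep", datetime(2016, 12, 23, 23), datetime(2016, 12, 24, 7))
        ]
        (session,) = extract_sleep_sessions(intervals)
        assert session.night == D0
        assert session.onset_hours == 23.0
        assert session.duration_s == 28800
        assert session.interruptions == 0

    def test_interrupted_night_counts_transition_and_sums_sleep(self):
        intervals = [
            _iv("Sleep", datetime(2016, 12, 23, 23), datetime(2016, 12, 24, 3)),
            _iv(
                "Bed_Toilet_Transition",
                datetime(2016, 12, 24, 3, 2),
                datetime(2016, 12, 24, 3, 8),
            ),
            _iv("Sleep", datetime(2016, 12, 24, 3, 10), datetime(2016, 12, 24, 7)),
        ]
        (session,) = extract_sleep_sessions(intervals)
        assert session.onset_hours == 23.0
        assert session.duration_s == 4 * 3600 + (3 * 3600 + 50 * 60)  # 28200
        assert session.interruptions == 1

    def test_gap_mode_counts_short_gaps_between_sleep_spans(self):
        intervals = [
            _iv("Sleep", datetime(2016, 12, 23, 23), datetime(2016, 12, 24, 3)),
            _iv("Sleep", datetime(2016, 12, 24, 3, 10), datetime(2016, 12, 24, 7)),
        ]
        (session,) = extract_sleep_sessions(intervals, interruption_mode="gap")
        assert session.interruptions == 1

    def test_night_without_sleep_listed_missing(self):
        intervals = [
            _iv("Sleep", datetime(2016, 12, 23, 23), datetime(2016, 12, 24, 7)),
            _iv(
                "Relax",
                datetime(2016, 12, 24, 15),
                datetime(2016, 12, 24, 16),
                night=date(2016, 12, 24),
            ),
        ]
        missing: list[date] = []
        sessions = extract_sleep_sessions(intervals, missing_nights=missing)
        assert [s.night for s in sessions] == [D0]
        assert missing == [date(2016, 12, 24)]


class TestBuildSleepReference:
    def test_identical_sessions_have_zero_spread(self):
        sessions = [SleepSession(D0 + timedelta(days=i), 23.0, 28800, 0) for i in range(4)]
        ref = build_sleep_reference(sessions)
        assert ref.onset_hours == pytest.approx(23.0)
        assert ref.duration_s == 28800
        assert ref.onset_sd_hours == pytest.approx(0.0, abs=1e-9)
        assert ref.duration_sd_s == 0.0

    def test_onsets_straddling_midnight_average_circularly(self):
        sessions = [
            SleepSession(D0, 23.5, 28800, 0),
            SleepSession(D0 + timedelta(days=1), 0.5, 28800, 0),
        ]
        ref = build_sleep_reference(sessions)
        # naive clock-hour mean would be 12.0; the circular mean is midnight
        assert compute_sod(ref.onset_hours, 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_duration_mean_and_population_sd(self):
        sessions = [
            SleepSession(D0, 23.0, 7 * 3600, 0),
            SleepSession(D0 + timedelta(days=1), 23.0, 9 * 3600, 0),
        ]
        ref = build_sleep_reference(sessions)
        assert ref.duration_s == pytest.approx(8 * 3600)
        assert ref.duration_sd_s == pytest.approx(3600)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_sleep_reference([])


class TestMetricFormulas:
    def test_sod_identity_and_wrap(self):
        assert compute_sod(23.0, 23.0) == 0.0
        assert compute_sod(23.5, 0.5) == pytest.approx(1.0)
        assert compute_sod(2.0, 22.0) == pytest.approx(4.0)

    def test_sod_symmetric(self):
        assert compute_sod(2.0, 22.0) == compute_sod(22.0, 2.0)

    def test_sod_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            compute_sod(24.0, 1.0)

    def test_sdd_in_hours(self):
        assert compute_sdd(28800, 28800) == 0.0
        assert compute_sdd(21600, 28800) == pytest.approx(2.0)
        assert compute_sdd(30600, 28800) == pytest.approx(0.5)

    def test_sdd_rejects_non_positive(self):
        with pytest.raises(ValueError):
            compute_sdd(0, 28800)

    def test_sii_per_hour(self):
        assert compute_sii(0, 8.0) == 0.0
        assert compute_sii(3, 6.0) == pytest.approx(0.5)

    def test_sii_undefined_for_zero_duration(self):
        with pytest.raises(ValueError):
            compute_sii(1, 0.0)

    def test_sci_perfect_clamped_and_mixed(self):
        assert compute_sci(0.0, 0.0, 28800) == 1.0
        assert compute_sci(12.0, 28800, 28800) == 0.0  # clamped at 0
        assert compute_sci(2.4, 0.1 * 28800, 28800) == pytest.approx(0.8)

    def test_sdp_weighted_sum(self):
        assert compute_sdp(0, 0, 0, 1.0) == 0.0
        assert compute_sdp(1, 2, 0.5, 0.8) == pytest.approx(0.925)
        assert compute_sdp(1, 1, 1, 1.0, SdpWeights(0.4, 0.3, 0.2, 0.1)) == pytest.approx(0.9)

    def test_negative_sdp_weight_rejected(self):
        with pytest.raises(ValueError):
            SdpWeights(w1=-0.1)


@given(
    st.lists(st.floats(0.0, 23.999), min_size=3, max_size=12),
    st.floats(0.0, 23.999),
)
@settings(derandomize=True, max_examples=100, deadline=None)
def test_onset_rotation_invariance(onsets, shift):
    """Shifting all onsets on the clock circle leaves spread and SOD fixed."""
    sessions = [
        SleepSession(D0 + timedelta(days=i), o, 28800, 0) for i, o in enumerate(onsets)
    ]
    rotated = [
        SleepSession(s.night, (s.onset_hours + shift) % 24.0, 28800, 0)
        for s in sessions
    ]
    ref = build_sleep_reference(sessions)
    ref_rot = build_sleep_reference(rotated)
    assert ref_rot.onset_sd_hours == pytest.approx(ref.onset_sd_hours, abs=1e-6)
    for s, sr in zip(sessions, rotated):
        assert compute_sod(sr.onset_hours, ref_rot.onset_hours % 24.0) == pytest.approx(
            compute_sod(s.onset_hours, ref.onset_hours % 24.0), abs=1e-6
        )


class TestScoringAndFlagging:
    def test_zero_variance_cohort_scores_zero(self):
        sessions = [SleepSession(D0 + timedelta(days=i), 23.0, 28800, 0) for i in range(10)]
        table = score_sleep_sessions(sessions)
        assert np.allclose(table["sdp"], 0.0, atol=1e-9)

    def test_constant_scores_dynamic_alpha_flags_nothing(self):
        scores = {D0 + timedelta(days=i): 0.3 for i in range(5)}
        records = flag_sleep_days(scores, ThresholdConfig("dynamic", alpha=1.0))
        assert not any(r.flagged for r in records)

    def test_single_outlier_in_flat_series_is_the_only_flag(self):
        scores = {D0 + timedelta(days=i): 0.1 for i in range(10)}
        outlier_day = D0 + timedelta(days=4)
        scores[outlier_day] = 2.0
        records = flag_sleep_days(scores, ThresholdConfig("dynamic", alpha=1.0))
        assert {r.day for r in records if r.flagged} == {outlier_day}

    def test_fixed_zero_threshold_flags_all_positive_scores(self):
        scores = {D0 + timedelta(days=i): s for i, s in enumerate([0.0, 0.1, 0.5])}
        records = flag_sleep_days(scores, ThresholdConfig("fixed", 0.0))
        assert [r.flagged for r in records] == [False, True, True]

    def test_sdp_monotone_in_each_component(self):
        base = compute_sdp(1.0, 1.0, 1.0, 0.5)
        assert compute_sdp(2.0, 1.0, 1.0, 0.5) > base
        assert compute_sdp(1.0, 2.0, 1.0, 0.5) > base
        assert compute_sdp(1.0, 1.0, 2.0, 0.5) > base
        assert compute_sdp(1.0, 1.0, 1.0, 0.9) < base  # higher consistency, lower score
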