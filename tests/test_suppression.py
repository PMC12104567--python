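"""Suppression-event detection against a brute-force per-sample oracle,
and the BSR aggregation arithmetic."""

import numpy as np
import pytest

from bsquant.sim_cohort import aged_eeg_preset, simulate_bs_eeg
from bsquant.suppression_metrics import (
    SuppressionEvent,
    bsr_global,
    bsr_timecourse,
    cumulative_suppression_time,
    detect_suppressions,
    summarize_suppression,
)

from helpers import brute_force_events, gap_fixture, make_recording, random_bursty_trace


class TestDetectRule:
    """The amplitude-duration rule: |x| <= 15 uV inclusive, > 0.2 s strict."""

    def test_all_zero_trace_is_one_event(self):
        rec = make_recording(np.zeros(20 * 250))
        events = detect_suppressions(rec)
        assert len(events) == 1
        assert (events[0].onset_s, events[0].offset_s) == (0.0, 20.0)

    def test_50uv_sinusoid_has_no_events(self):
        # each sub-threshold run near a zero crossing of a 10 Hz, 50 uV tone
        # lasts ~2*arcsin(15/50)/(2*pi*10) ~ 0.0097 s, far below 0.2 s
        t = np.arange(10 * 250) / 250.0
        rec = make_recording(50 * np.sin(2 * np.pi * 10 * t))
        assert detect_suppressions(rec, filter_band=None) == []

    def test_inserted_gap_detected_exactly(self):
        x = gap_fixture()
        rec = make_recording(x)
        events = detect_suppressions(rec, filter_band=None)
        oracle = brute_force_events(x, 250.0)
        assert [(e.onset_s, e.offset_s) for e in events] == oracle
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(1.0, abs=1 / 250)

    def test_duration_boundary_is_strict(self):
        # exactly 0.2 s (50 samples at 250 Hz) within threshold: excluded;
        # 51 samples: included
        fs = 250
        for k, expected in [(50, 0), (51, 1)]:
            x = np.concatenate([np.full(fs, 100.0), np.zeros(k), np.full(fs, 100.0)])
            events = detect_suppressions(make_recording(x), filter_band=None)
            assert len(events) == expected, f"run of {k} samples"

    def test_amplitude_boundary_is_inclusive(self):
        # samples at exactly 15 uV count as suppressed
        x = np.concatenate([np.full(250, 100.0), np.full(100, 15.0), np.full(250, 100.0)])
        events = detect_suppressions(make_recording(x), filter_band=None)
        assert len(events) == 1
        assert events[0].duration_s == pytest.approx(0.4)

    def test_empty_recording_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_suppressions(make_recording(np.array([])))


class TestOracleEquivalence:
    def test_random_traces_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            x = random_bursty_trace(rng)
            events = detect_suppressions(make_recording(x), filter_band=None)
            assert [(e.onset_s, e.offset_s) for e in events] == brute_force_events(x, 250.0)

    def test_monotonicity_in_threshold_and_duration(self):
        rng = np.random.default_rng(43)
        window = (0.0, 10.0)
        for _ in range(10):
            x = random_bursty_trace(rng)
            rec = make_recording(x)
            totals_thr = [
                cumulative_suppression_time(
                    detect_suppressions(rec, threshold_uv=thr, filter_band=None), window
                )
                for thr in (5.0, 15.0, 30.0)
            ]
            assert totals_thr == sorted(totals_thr)
            totals_dur = [
                cumulative_suppression_time(
                    detect_suppressions(rec, min_duration_s=d, filter_band=None), window
                )
                for d in (0.0, 0.2, 1.0)
            ]
            assert totals_dur == sorted(totals_dur, reverse=True)

    def test_translation_invariance(self):
        rng = np.random.default_rng(44)
        x = random_bursty_trace(rng)
        shift = 500  # samples, all above threshold so no run is created/merged
        pad = np.full(shift, 100.0)
        ev0 = detect_suppressions(make_recording(x), filter_band=None)
        ev1 = detect_suppressions(make_recording(np.concatenate([pad, x])), filter_band=None)
        assert len(ev0) == len(ev1)
        shifted = np.array([(e.onset_s + shift / 250.0, e.offset_s + shift / 250.0) for e in ev0])
        np.testing.assert_allclose(
            shifted, np.array([(e.onset_s, e.offset_s) for e in ev1]), atol=1e-9
        )


class TestAggregation:
    def test_cumulative_time_direct_sum(self):
        events = [SuppressionEvent(10, 20), SuppressionEvent(30, 35)]
        assert cumulative_suppression_time(events, (0, 60)) == 15.0

    def test_straddling_event_clipped(self):
        assert cumulative_suppression_time([SuppressionEvent(18, 25)], (20, 60)) == 5.0

    def test_no_events_is_zero(self):
        assert cumulative_suppression_time([], (0, 60)) == 0.0

    def test_unsorted_events_rejected(self):
        events = [SuppressionEvent(30, 35), SuppressionEvent(10, 20)]
        with pytest.raises(ValueError, match="sorted"):
            cumulative_suppression_time(events, (0, 60))

    def test_overlapping_events_rejected(self):
        events = [SuppressionEvent(10, 20), SuppressionEvent(15, 25)]
        with pytest.raises(ValueError, match="overlap"):
            cumulative_suppression_time(events, (0, 60))

    def test_bsr_percentages(self):
        events = [SuppressionEvent(0, 15)]
        assert bsr_global(events, (0, 60)) == pytest.approx(25.0)
        assert bsr_global([SuppressionEvent(0, 60)], (0, 60)) == pytest.approx(100.0)

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError, match="positive length"):
            bsr_global([], (10, 10))

    def test_summary_consistency(self):
        events = [SuppressionEvent(5, 10), SuppressionEvent(50, 70)]
        s = summarize_suppression(events, (0.0, 60.0))
        assert s.total_suppression_time_s == pytest.approx(15.0)
        assert s.bsr_percent == pytest.approx(100 * 15 / 60, abs=1e-9)
        assert s.n_events == 2


class TestTimecourse:
    def _rec(self, n_s=300):
        return make_recording(np.zeros(n_s * 250), anesthesia_start_s=0.0,
                              anesthesia_end_s=float(n_s))

    def test_full_suppression_every_window_100(self):
        rec = self._rec()
        events = [SuppressionEvent(0.0, 300.0)]
        tc = bsr_timecourse(rec, events)
        assert np.allclose(tc.bsr_percent, 100.0)

    def test_nonoverlapping_windows_average_to_global(self):
        rec = self._rec()
        events = [SuppressionEvent(10.0, 35.0), SuppressionEvent(100.0, 170.5)]
        tc = bsr_timecourse(rec, events, win_s=60.0, step_s=60.0)
        assert np.mean(tc.bsr_percent) == pytest.approx(
            bsr_global(events, (0.0, 300.0)), abs=1e-9
        )

    def test_suppression_in_first_half_only_decays(self):
        rec = self._rec()
        events = [SuppressionEvent(0.0, 150.0)]
        tc = bsr_timecourse(rec, events)
        mid = np.searchsorted(tc.window_centers_s, 150.0)
        tail = tc.bsr_percent[mid:]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_window_longer_than_anesthesia_rejected(self):
        rec = self._rec(30)
        with pytest.raises(ValueError, match="win_s"):
            bsr_timecourse(rec, [], win_s=60.0)


def test_detected_bsr_tracks_ground_truth():
    """Aged preset: detected BSR within 5 points of the generative truth."""
    rec, truth = simulate_bs_eeg(aged_eeg_preset(seed=5))
    events = detect_suppressions(rec)
    bsr = bsr_global(events, rec.anesthesia_window)
    assert abs(bsr - truth.true_bsr_percent) <= 5.0
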