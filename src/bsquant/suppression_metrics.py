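"""Suppression-event detection and burst-suppression ratio (BSR).

A *suppression event* is a maximal run of samples whose absolute amplitude
stays within a threshold (default +/-15 uV, inclusive) for strictly longer
than a minimum duration (default 0.2 s).  The *cumulative suppression time*
over an analysis window is the summed length of the intersections of all
events with that window, and the BSR is that time as a percentage of the
window length.  Windows and events are half-open intervals in seconds.

By default detection runs on the 0.5-70 Hz recording band
(:func:`bsquant.eeg_io.bandpass_filter`); pass ``filter_band=None`` to
detect on the raw samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import EEGRecording, bandpass_filter

__all__ = [
    "SuppressionEvent",
    "SuppressionSummary",
    "BSRTimecourse",
    "detect_suppressions",
    "cumulative_suppression_time",
    "bsr_global",
    "bsr_timecourse",
    "summarize_suppression",
]

DEFAULT_THRESHOLD_UV = 15.0
DEFAULT_MIN_DURATION_S = 0.2


@dataclass(frozen=True)
class SuppressionEvent:
    """Half-open isoelectric interval ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class SuppressionSummary:
    window_start_s: float
    window_end_s: float
    total_suppression_time_s: float
    bsr_percent: float
    n_events: int


@dataclass(frozen=True)
class BSRTimecourse:
    window_centers_s: np.ndarray
    bsr_percent: np.ndarray
    win_s: float
    step_s: float


def _runs_within_threshold(x: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (start, stop) of samples with |x| <= threshold, half-open
    in sample indices."""
    mask = np.abs(x) <= threshold
    if not mask.any():
        return []
    # boundaries of True runs via the padded difference trick
    d = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_suppressions(
    rec: EEGRecording,
    threshold_uv: float = DEFAULT_THRESHOLD_UV,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    filter_band: tuple[float, float] | None = (0.5, 70.0),
) -> list[SuppressionEvent]:
    """Detect suppression events by the amplitude-duration rule.

    The amplitude comparison is inclusive (``|x| <= threshold_uv`` counts as
    suppressed) and the duration comparison strict (a run of ``k`` samples
    spans ``k/fs`` seconds and is kept iff ``k/fs > min_duration_s``).  Runs
    touching the record edges are kept; their observed duration is a lower
    bound on the true one.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot detect suppressions in an empty recording")
    if threshold_uv <= 0:
        raise ValueError(f"threshold_uv must be positive, got {threshold_uv}")
    if min_duration_s < 0:
        raise ValueError(f"min_duration_s must be >= 0, got {min_duration_s}")
    if filter_band is not None:
        rec = bandpass_filter(rec, *filter_band)
    fs = rec.fs_hz
    events = [
        SuppressionEvent(onset_s=start / fs, offset_s=stop / fs)
        for start, stop in _runs_within_threshold(rec.samples_uv, threshold_uv)
        if (stop - start) / fs > min_duration_s
    ]
    return events


def _validate_events(events: list[SuppressionEvent]) -> None:
    prev_end = -np.inf
    for ev in events:
        if ev.offset_s <= ev.onset_s:
            raise ValueError(f"event {ev} has non-positive duration")
        if ev.onset_s < prev_end:
            raise ValueError("events must be sorted and non-overlapping")
        prev_end = ev.offset_s


def cumulative_suppression_time(
    events: list[SuppressionEvent], window: tuple[float, float]
) -> float:
    """Sum of event-window intersection lengths, in seconds.

    Events straddling a window edge contribute only their intersection with
    the half-open window ``[start, end)``.
    """
    start, end = window
    if not end > start:
        raise ValueError(f"window [{start}, {end}) must have positive length")
    _validate_events(events)
    total = 0.0
    for ev in events:
        total += max(0.0, min(ev.offset_s, end) - max(ev.onset_s, start))
    return total


def bsr_global(events: list[SuppressionEvent], window: tuple[float, float]) -> float:
    """Burst-suppression ratio: percent of the window spent in suppression."""
    start, end = window
    if not end > start:
        raise ValueError(f"window [{start}, {end}) must have positive length")
    return 100.0 * cumulative_suppression_time(events, window) / (end - start)


def bsr_timecourse(
    rec: EEGRecording,
    events: list[SuppressionEvent],
    win_s: float = 60.0,
    step_s: float = 10.0,
) -> BSRTimecourse:
    """Sliding-window BSR over the anesthesia interval.

    Windows are half-open ``[t, t + win_s)`` starting at the anesthesia
    onset and advancing by ``step_s``; a partial trailing window is dropped.
    """
    if win_s <= 0 or step_s <= 0:
        raise ValueError("win_s and step_s must be positive")
    a_start, a_end = rec.anesthesia_window
    if win_s > a_end - a_start:
        raise ValueError(
            f"win_s={win_s} exceeds the anesthesia window length {a_end - a_start}"
        )
    centers, values = [], []
    t = a_start
    while t + win_s <= a_end + 1e-9:
        values.append(bsr_global(events, (t, t + win_s)))
        centers.append(t + win_s / 2)
        t += step_s
    return BSRTimecourse(
        window_centers_s=np.asarray(centers),
        bsr_percent=np.asarray(values),
        win_s=win_s,
        step_s=step_s,
    )


def summarize_suppression(
    events: list[SuppressionEvent], window: tuple[float, float]
) -> SuppressionSummary:
    """Cumulative suppression time, BSR and event count over a window.

    ``n_events`` counts events intersecting the window.
    """
    start, end = window
    total = cumulative_suppression_time(events, window)
    n = sum(1 for ev in events if min(ev.offset_s, end) - max(ev.onset_s, start) > 0)
    return SuppressionSummary(
        window_start_s=start,
        window_end_s=end,
        total_suppression_time_s=total,
        bsr_percent=100.0 * total / (end - start),
        n_events=n,
    )
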