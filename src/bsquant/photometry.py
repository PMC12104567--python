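"""Fiber-photometry dF/F computation and pre/during-anesthesia quantification.

dF/F is the gauge-invariant fluorescence change (F - F0)/F0, where F0 is
the mean raw fluorescence over a baseline control window — by default the
100 s immediately preceding anesthesia onset.  No detrending or isosbestic
(405 nm reference) correction is applied; if a rig records a reference
channel, correct it upstream before computing dF/F here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eeg_io import PhotometryTrace

__all__ = [
    "DffTrace",
    "EpochChange",
    "GroupMeanTrace",
    "DEFAULT_BASELINE_S",
    "default_baseline_window",
    "compute_dff",
    "epoch_change",
    "group_mean_trace",
]

DEFAULT_BASELINE_S = 100.0


@dataclass
class DffTrace:
    """Baseline-normalized fluorescence change, same length as its source."""

    dff: np.ndarray
    fs_hz: float
    f0_au: float
    baseline_start_s: float
    baseline_end_s: float
    anesthesia_start_s: float | None = None
    anesthesia_end_s: float | None = None
    subject_id: str = ""
    group_label: str | None = None

    @property
    def n_samples(self) -> int:
        return self.dff.size

    @property
    def duration_s(self) -> float:
        return self.dff.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.dff.size) / self.fs_hz


@dataclass(frozen=True)
class EpochChange:
    pre_mean: float
    during_mean: float
    change: float  # during - pre


@dataclass(frozen=True)
class GroupMeanTrace:
    times_s: np.ndarray  # relative to the alignment point
    mean: np.ndarray
    sem: np.ndarray
    n: int


def default_baseline_window(
    trace: PhotometryTrace, baseline_s: float = DEFAULT_BASELINE_S
) -> tuple[float, float]:
    """The ``baseline_s`` seconds of control time ending at anesthesia onset
    (clipped to the record start)."""
    if trace.anesthesia_start_s is None:
        raise ValueError(
            "trace has no anesthesia annotation; pass baseline_window explicitly"
        )
    end = trace.anesthesia_start_s
    return (max(0.0, end - baseline_s), end)


def _window_slice(n: int, fs: float, window: tuple[float, float]) -> slice:
    start, end = window
    if not (0 <= start < end <= n / fs + 1e-9):
        raise ValueError(f"window [{start}, {end}) outside trace of {n / fs:.1f} s")
    return slice(int(round(start * fs)), int(round(end * fs)))


def compute_dff(
    trace: PhotometryTrace, baseline_window: tuple[float, float] | None = None
) -> DffTrace:
    """dF/F = (F - F0)/F0 with F0 the baseline-window mean of F."""
    if baseline_window is None:
        baseline_window = default_baseline_window(trace)
    sel = _window_slice(trace.n_samples, trace.fs_hz, baseline_window)
    f0 = float(np.mean(trace.f_au[sel]))
    if f0 <= 0:
        raise ValueError(f"baseline mean fluorescence must be positive, got {f0}")
    return DffTrace(
        dff=(trace.f_au - f0) / f0,
        fs_hz=trace.fs_hz,
        f0_au=f0,
        baseline_start_s=baseline_window[0],
        baseline_end_s=baseline_window[1],
        anesthesia_start_s=trace.anesthesia_start_s,
        anesthesia_end_s=trace.anesthesia_end_s,
        subject_id=trace.subject_id,
        group_label=trace.group_label,
    )


def epoch_change(
    dff: DffTrace,
    pre_window: tuple[float, float] | None = None,
    during_window: tuple[float, float] | None = None,
) -> EpochChange:
    """Mean dF/F before vs. during anesthesia, and their difference.

    Defaults: ``pre`` is the baseline window used for F0 and ``during`` the
    annotated anesthesia window.  Windows must not overlap.
    """
    if pre_window is None:
        pre_window = (dff.baseline_start_s, dff.baseline_end_s)
    if during_window is None:
        if dff.anesthesia_start_s is None:
            raise ValueError("no anesthesia annotation; pass during_window explicitly")
        during_window = (dff.anesthesia_start_s, dff.anesthesia_end_s)
    lo, hi = sorted([pre_window, during_window])
    if lo[1] > hi[0]:
        raise ValueError(f"windows {pre_window} and {during_window} overlap")
    pre = float(np.mean(dff.dff[_window_slice(dff.n_samples, dff.fs_hz, pre_window)]))
    dur = float(np.mean(dff.dff[_window_slice(dff.n_samples, dff.fs_hz, during_window)]))
    return EpochChange(pre_mean=pre, during_mean=dur, change=dur - pre)


def group_mean_trace(
    dffs: list[DffTrace], align_at_s: list[float] | None = None
) -> GroupMeanTrace:
    """Per-timepoint mean and SEM across subjects, aligned at anesthesia onset.

    Traces are aligned at ``align_at_s`` (default: each trace's annotated
    anesthesia onset) and truncated to the common support; SEM = SD/sqrt(n)
    with the unbiased (ddof=1) SD.
    """
    if len(dffs) < 2:
        raise ValueError("need at least 2 traces for a group SEM")
    fs = dffs[0].fs_hz
    if any(abs(d.fs_hz - fs) > 1e-9 for d in dffs):
        raise ValueError("all traces must share the sampling rate")
    if align_at_s is None:
        if any(d.anesthesia_start_s is None for d in dffs):
            raise ValueError("missing anesthesia annotations; pass align_at_s")
        align_at_s = [d.anesthesia_start_s for d in dffs]
    anchors = [int(round(a * fs)) for a in align_at_s]
    for d, a in zip(dffs, anchors):
        if not (0 <= a < d.n_samples):
            raise ValueError("alignment time outside a trace")
    pre = min(anchors)
    post = min(d.n_samples - a for d, a in zip(dffs, anchors))
    stack = np.stack([d.dff[a - pre : a + post] for d, a in zip(dffs, anchors)])
    n = stack.shape[0]
    return GroupMeanTrace(
        times_s=(np.arange(-pre, post)) / fs,
        mean=stack.mean(axis=0),
        sem=stack.std(axis=0, ddof=1) / np.sqrt(n),
        n=n,
    )
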