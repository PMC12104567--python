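"""Shared test oracles and fixture builders."""

from __future__ import annotations

import numpy as np

from bsquant.eeg_io import EEGRecording


def brute_force_events(
    x, fs: float, threshold: float = 15.0, min_duration_s: float = 0.2
) -> list[tuple[float, float]]:
    """Per-sample run scanner: the independent oracle for suppression
    detection.  Walks the samples one by one, tracks maximal runs with
    |x| <= threshold, and keeps runs spanning strictly more than
    ``min_duration_s`` (a k-sample run spans k/fs seconds)."""
    events = []
    run_start = None
    for i, v in enumerate(x):
        if abs(v) <= threshold:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                if (i - run_start) / fs > min_duration_s:
                    events.append((run_start / fs, i / fs))
                run_start = None
    if run_start is not None and (len(x) - run_start) / fs > min_duration_s:
        events.append((run_start / fs, len(x) / fs))
    return events


def make_recording(x, fs: float = 250.0, **kwargs) -> EEGRecording:
    return EEGRecording(samples_uv=np.asarray(x, dtype=float), fs_hz=fs, **kwargs)


def gap_fixture(fs: int = 250, seed: int = 0) -> np.ndarray:
    """5 s of RMS-40 noise, a 1.0 s exact-zero gap, 5 s of noise.

    With this seed the samples adjacent to the gap exceed the 15 uV
    threshold, so the hand-enumerated event is exactly the zero run
    [5.0 s, 6.0 s).
    """
    rng = np.random.default_rng(seed)
    return np.concatenate(
        [rng.normal(0, 40, 5 * fs), np.zeros(fs), rng.normal(0, 40, 5 * fs)]
    )


def random_bursty_trace(rng: np.random.Generator, fs: int = 250, dur_s: float = 10.0):
    """Random mixed-amplitude trace for oracle-equivalence checks: random
    segments of white noise at SDs spanning well below and well above the
    15 uV threshold."""
    n = int(dur_s * fs)
    x = np.empty(n)
    i = 0
    sds = [2.0, 5.0, 8.0, 20.0, 40.0]
    while i < n:
        seg = int(rng.integers(10, 2 * fs))
        sd = sds[rng.integers(len(sds))]
        j = min(n, i + seg)
        x[i:j] = rng.normal(0, sd, j - i)
        i = j
    return x
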