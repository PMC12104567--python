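"""Spectrograms and relative band power for anesthesia EEG.

Band power is reported for the four conventional rodent EEG bands

    delta [0.5, 4) Hz,  theta [4, 8) Hz,  alpha [8, 15) Hz,  beta [15, 25) Hz

as a *composition*: each band's power divided by the total power over the
union of the four bands (0.5-25 Hz), so the four fractions sum to 1.  Band
edges are half-open so shared edges (4, 8, 15 Hz) are never double-counted.

PSDs come from Welch's method with 2-s Hamming segments (0.5 Hz resolution
at 250 Hz); band power is the Riemann sum PSD*df over frequency bins in
[lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import EEGRecording

__all__ = ["Spectrogram", "BandPowerTable", "DEFAULT_BANDS", "spectrogram", "relative_band_power"]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 25.0),
}


@dataclass(frozen=True)
class Spectrogram:
    times_s: np.ndarray       # segment centers
    freqs_hz: np.ndarray
    power: np.ndarray         # PSD, uV^2/Hz, shape (n_freqs, n_times)


@dataclass(frozen=True)
class BandPowerTable:
    bands: dict[str, tuple[float, float]]
    band_power: dict[str, float]       # absolute, uV^2
    relative_power: dict[str, float]   # fractions over the band union
    window_start_s: float
    window_end_s: float


def spectrogram(
    rec: EEGRecording, seg_s: float = 2.0, overlap: float = 0.75
) -> Spectrogram:
    """Short-time PSD (Hamming taper, one-sided density scaling).

    Per-segment Parseval consistency (sum power*df ~ segment variance) is a
    property of the density scaling and is exercised in the test suite.
    """
    nper = int(round(seg_s * rec.fs_hz))
    if nper < 8:
        raise ValueError(f"segment of {seg_s} s gives {nper} samples; need >= 8")
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if nper > rec.n_samples:
        raise ValueError("segment longer than the record")
    freqs, times, power = sps.spectrogram(
        rec.samples_uv,
        fs=rec.fs_hz,
        window=sps.get_window("hamming", nper),
        nperseg=nper,
        noverlap=int(round(overlap * nper)),
        scaling="density",
        mode="psd",
        detrend=False,
    )
    return Spectrogram(times_s=times, freqs_hz=freqs, power=power)


def relative_band_power(
    rec: EEGRecording,
    window: tuple[float, float] | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    seg_s: float = 2.0,
    overlap: float = 0.5,
) -> BandPowerTable:
    """Welch band power over a window, normalized over the band union.

    ``window`` defaults to the recording's anesthesia window.  The
    denominator is the total power over the union of the requested bands
    (0.5-25 Hz for the defaults); switch ``bands`` to change either the
    partition or the denominator.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    if window is None:
        window = rec.anesthesia_window
    start, end = window
    if not (0 <= start < end <= rec.duration_s + 1e-9):
        raise ValueError(f"window [{start}, {end}) outside the record")
    if end - start < 8.0:
        raise ValueError(f"window of {end - start:.1f} s too short; need >= 8 s")
    i0, i1 = int(round(start * rec.fs_hz)), int(round(end * rec.fs_hz))
    x = rec.samples_uv[i0:i1]
    nper = int(round(seg_s * rec.fs_hz))
    freqs, psd = sps.welch(
        x,
        fs=rec.fs_hz,
        window=sps.get_window("hamming", nper),
        nperseg=nper,
        noverlap=int(round(overlap * nper)),
        scaling="density",
        detrend=False,
    )
    df = freqs[1] - freqs[0]
    band_power: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        band_power[name] = float(np.sum(psd[sel]) * df)
    total = sum(band_power.values())
    if total <= 0:
        rel = {name: 0.0 for name in bands}
    else:
        rel = {name: p / total for name, p in band_power.items()}
    return BandPowerTable(
        bands=dict(bands),
        band_power=band_power,
        relative_power=rel,
        window_start_s=start,
        window_end_s=end,
    )
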