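"""Reading, writing and band-filtering of EEG and fiber-photometry traces.

Two on-disk formats are supported for EEG: EDF (European Data Format,
16-bit) and a plain two-column TSV ``time_s<TAB>amplitude_uv``.  Photometry
traces use the analogous TSV ``time_s<TAB>F_au``.  Anesthesia-window
annotations travel in a JSON sidecar next to the data file
(``<stem>.annotations.json`` with keys ``anesthesia_start_s`` and
``anesthesia_end_s``); the half-open convention ``[start, end)`` is used
throughout, with time in seconds from record start.

EDF reading is delegated to :func:`mne.io.read_raw_edf`.  Writing uses a
minimal single-channel 16-bit EDF encoder (1-second data records, physical
unit microvolt) so that written files round-trip through the independent
MNE reader within one quantization step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "PhotometryTrace",
    "read_eeg",
    "write_eeg",
    "read_photometry",
    "write_photometry",
    "bandpass_filter",
]


class ParseError(ValueError):
    """Malformed input file (header, timebase, or missing columns)."""


@dataclass
class EEGRecording:
    """Single-channel EEG amplitude series in microvolts.

    ``anesthesia_start_s`` / ``anesthesia_end_s`` delimit the half-open
    anesthesia window ``[start, end)`` in seconds from record start; both
    are ``None`` when no annotation is available.
    """

    samples_uv: np.ndarray
    fs_hz: float
    start_time_s: float = 0.0
    anesthesia_start_s: float | None = None
    anesthesia_end_s: float | None = None
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.samples_uv = np.asarray(self.samples_uv, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.samples_uv.ndim != 1:
            raise ValueError("samples_uv must be one-dimensional")
        if self.samples_uv.size and not np.all(np.isfinite(self.samples_uv)):
            raise ValueError("samples_uv contains non-finite values")
        if (self.anesthesia_start_s is None) != (self.anesthesia_end_s is None):
            raise ValueError("anesthesia window needs both start and end")
        if self.anesthesia_start_s is not None:
            if not (0 <= self.anesthesia_start_s < self.anesthesia_end_s <= self.duration_s + 1e-9):
                raise ValueError(
                    "anesthesia window [%g, %g) must satisfy 0 <= start < end <= %g"
                    % (self.anesthesia_start_s, self.anesthesia_end_s, self.duration_s)
                )

    @property
    def n_samples(self) -> int:
        return self.samples_uv.size

    @property
    def duration_s(self) -> float:
        return self.samples_uv.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.fs_hz

    @property
    def anesthesia_window(self) -> tuple[float, float]:
        """Analysis window: the annotated anesthesia interval, else the full record."""
        if self.anesthesia_start_s is None:
            return (0.0, self.duration_s)
        return (self.anesthesia_start_s, self.anesthesia_end_s)


@dataclass
class PhotometryTrace:
    """Raw fluorescence series in arbitrary units."""

    f_au: np.ndarray
    fs_hz: float
    anesthesia_start_s: float | None = None
    anesthesia_end_s: float | None = None
    subject_id: str = ""
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.f_au = np.asarray(self.f_au, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.f_au.size and not np.all(np.isfinite(self.f_au)):
            raise ValueError("f_au contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.f_au.size

    @property
    def duration_s(self) -> float:
        return self.f_au.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.f_au.size) / self.fs_hz


# ---------------------------------------------------------------------------
# sidecar annotations
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.stem + ".annotations.json")


def _read_sidecar(path: Path) -> tuple[float | None, float | None]:
    sc = _sidecar_path(path)
    if not sc.exists():
        return None, None
    meta = json.loads(sc.read_text())
    return meta.get("anesthesia_start_s"), meta.get("anesthesia_end_s")


def _write_sidecar(path: Path, start: float | None, end: float | None) -> None:
    if start is None:
        return
    sc = _sidecar_path(path)
    sc.write_text(
        json.dumps({"anesthesia_start_s": start, "anesthesia_end_s": end}, indent=1)
        + "\n"
    )


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def _read_tsv_two_col(path: Path, value_col: str) -> tuple[np.ndarray, float]:
    """Read ``time_s<TAB><value_col>``, return (values, fs) after checking the
    timebase is uniform within 1 ppm."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", value_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    x = df[value_col].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples to infer sampling rate")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise ParseError(f"{path}: non-increasing time column")
    if np.max(np.abs(dt - dt_med)) > 1e-6 * dt_med:
        raise ParseError(f"{path}: time steps not uniform within 1 ppm")
    return x, 1.0 / dt_med


# ---------------------------------------------------------------------------
# EDF (single channel, 16-bit)
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {value!r} exceeds {width} bytes")
    return b.ljust(width)


def _write_edf(path: Path, x: np.ndarray, fs: float, label: str = "EEG") -> None:
    # 1-second data records keep the record size well under the EDF cap;
    # that requires an integer sampling rate and a whole number of seconds.
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF output requires an integer sampling rate, got {fs}; use TSV")
    spr = int(round(fs))
    if x.size % spr != 0:
        raise ValueError(
            f"EDF output requires a whole number of 1-s records "
            f"({x.size} samples at {spr} Hz); use TSV"
        )
    n_rec = x.size // spr
    phys_max = max(1.0, float(np.max(np.abs(x))))
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767

    f = _edf_field
    hdr = b"".join(
        [
            f("0", 8),                      # version
            f("X X X X", 80),               # patient id (anonymous)
            f("Startdate X X X X", 80),     # recording id
            f("01.01.00", 8),               # start date
            f("00.00.00", 8),               # start time
            f(256 + 256, 8),                # header bytes: fixed + 1 signal
            f("", 44),                      # reserved
            f(n_rec, 8),
            f(1, 8),                        # record duration, seconds
            f(1, 4),                        # number of signals
            f(label, 16),
            f("", 80),                      # transducer
            f("uV", 8),
            f("%g" % phys_min, 8),
            f("%g" % phys_max, 8),
            f(dig_min, 8),
            f(dig_max, 8),
            f("", 80),                      # prefiltering
            f(spr, 8),
            f("", 32),                      # reserved
        ]
    )
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((x - phys_min) / scale + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(digital.tobytes())


def _read_edf(path: Path) -> tuple[np.ndarray, float]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    # MNE rescales microvolt channels to volts internally.
    x = raw.get_data()[0] * 1e6
    return np.asarray(x, dtype=float), fs


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".tsv", ".txt", ".csv"):
        return "tsv"
    raise ParseError(f"cannot infer format from suffix {suffix!r}; pass format explicitly")


def read_eeg(path, fmt: str = "auto", subject_id: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or TSV.

    The sampling rate comes from the EDF header or, for TSV, from the median
    time step (which must be uniform within 1 ppm).  Anesthesia annotations
    are picked up from a ``<stem>.annotations.json`` sidecar when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        try:
            x, fs = _read_edf(path)
        except FileNotFoundError:
            raise
        except Exception as exc:  # mne raises various types on bad headers
            raise ParseError(f"{path}: not a readable EDF file ({exc})") from exc
    elif fmt == "tsv":
        x, fs = _read_tsv_two_col(path, "amplitude_uv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    start, end = _read_sidecar(path)
    return EEGRecording(
        samples_uv=x,
        fs_hz=fs,
        anesthesia_start_s=start,
        anesthesia_end_s=end,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_eeg(rec: EEGRecording, path, fmt: str = "auto") -> None:
    """Write a recording as EDF (16-bit) or TSV (full float precision)."""
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "edf":
        _write_edf(path, rec.samples_uv, rec.fs_hz)
    elif fmt == "tsv":
        t = rec.times_s
        with open(path, "w") as fh:
            fh.write("time_s\tamplitude_uv\n")
            for ti, xi in zip(t, rec.samples_uv):
                fh.write(f"{ti:.9g}\t{xi:.17g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    _write_sidecar(path, rec.anesthesia_start_s, rec.anesthesia_end_s)


def read_photometry(path, subject_id: str | None = None) -> PhotometryTrace:
    """Read a photometry TSV ``time_s<TAB>F_au`` (+ optional sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    x, fs = _read_tsv_two_col(path, "F_au")
    start, end = _read_sidecar(path)
    return PhotometryTrace(
        f_au=x,
        fs_hz=fs,
        anesthesia_start_s=start,
        anesthesia_end_s=end,
        subject_id=subject_id if subject_id is not None else path.stem,
    )


def write_photometry(trace: PhotometryTrace, path) -> None:
    if trace.n_samples == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s\tF_au\n")
        for ti, xi in zip(trace.times_s, trace.f_au):
            fh.write(f"{ti:.9g}\t{xi:.17g}\n")
    _write_sidecar(path, trace.anesthesia_start_s, trace.anesthesia_end_s)


# ---------------------------------------------------------------------------
# recording-band filter
# ---------------------------------------------------------------------------

def bandpass_filter(
    rec: EEGRecording,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    zero_phase: bool = True,
) -> EEGRecording:
    """Apply the recording-band filter (default 0.5-70 Hz).

    A 4th-order Butterworth bandpass run forward-backward
    (:func:`scipy.signal.sosfiltfilt`) so that suppression-event onset and
    offset times are not delayed by filter group delay; ``zero_phase=False``
    gives the causal single-pass variant.  Output length and all metadata
    equal the input's.
    """
    if not (0 < low_hz < high_hz < rec.fs_hz / 2):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low_hz}, high={high_hz}, fs={rec.fs_hz}"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=rec.fs_hz, output="sos")
    if zero_phase:
        y = sps.sosfiltfilt(sos, rec.samples_uv)
    else:
        y = sps.sosfilt(sos, rec.samples_uv)
    return replace(rec, samples_uv=y)
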