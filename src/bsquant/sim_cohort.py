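"""Synthetic young/aged anesthesia cohorts with ground truth.

The EEG generator is a phenomenological alternating-renewal model of burst
suppression: inside the anesthesia window the signal alternates between a
*burst* state (band-weighted colored noise at a configurable RMS) and a
*suppression* state (low-amplitude white noise), with i.i.d. state
durations drawn from an exponential or gamma law.  Outside the window an
awake-like band-weighted signal at intermediate RMS is produced.  Raised-
cosine amplitude ramps (default 50 ms) at state changes avoid spectral
splatter from step edges; ground-truth labels switch at the ramp midpoint.

The photometry generator emulates an ATP-sensor fluorescence trace: flat
baseline (young phenotype) or a saturating exponential decline after
anesthesia onset (aged phenotype), plus linear photobleaching drift and
white noise.

Cohort-level generation adds per-subject behavioral emergence times
(lognormal), qPCR Ct tables, densitometry tables, and a scalar tissue-ATP
assay, so the full downstream analysis runs with no external data.  Every
generator is a pure function of its config (seed included): identical
configs give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .eeg_io import (
    EEGRecording,
    PhotometryTrace,
    write_eeg,
    write_photometry,
)
from .spectral_metrics import DEFAULT_BANDS

__all__ = [
    "ConfigError",
    "BSSimConfig",
    "PhotometrySimConfig",
    "GroupSpec",
    "CohortSpec",
    "GroundTruth",
    "LABEL_AWAKE",
    "LABEL_BURST",
    "LABEL_SUPPRESSION",
    "simulate_bs_eeg",
    "simulate_photometry",
    "simulate_cohort",
    "ground_truth_bsr",
    "young_eeg_preset",
    "aged_eeg_preset",
    "young_photometry_preset",
    "aged_photometry_preset",
    "young_group_preset",
    "aged_group_preset",
    "demo_cohort_spec",
]

LABEL_AWAKE = 0
LABEL_BURST = 1
LABEL_SUPPRESSION = 2
LABEL_NAMES = {LABEL_AWAKE: "awake", LABEL_BURST: "burst", LABEL_SUPPRESSION: "suppression"}


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


def _default_band_weights() -> dict[str, float]:
    return {"delta": 0.4, "theta": 0.2, "alpha": 0.2, "beta": 0.2}


@dataclass(frozen=True)
class BSSimConfig:
    """Generative specification for one burst-suppression EEG recording.

    ``mean_suppression_s`` / ``mean_burst_s`` are the means of the state-
    duration law (``exponential`` or ``gamma`` with shape ``gamma_shape``),
    so the asymptotic BSR is ``100 * mean_supp / (mean_supp + mean_burst)``.
    ``sigma_suppression_uv`` must stay below 5 uV so suppression samples fall
    within the +/-15 uV detection threshold with per-sample probability
    > 0.997 (3-sigma rule).
    """

    seed: int
    duration_s: float = 1500.0
    fs_hz: float = 250.0
    anesthesia_start_s: float = 200.0
    anesthesia_end_s: float = 1400.0
    mean_suppression_s: float = 5.0
    mean_burst_s: float = 5.0
    duration_law: str = "exponential"  # or "gamma"
    gamma_shape: float = 2.0
    sigma_suppression_uv: float = 4.0
    burst_rms_uv: float = 40.0
    band_weights: dict[str, float] = field(default_factory=_default_band_weights)
    transition_ramp_s: float = 0.05
    pre_anesthesia_rms_uv: float = 25.0

    def validate(self) -> None:
        for name in ("duration_s", "fs_hz", "mean_suppression_s", "mean_burst_s",
                     "burst_rms_uv", "pre_anesthesia_rms_uv"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 <= self.anesthesia_start_s < self.anesthesia_end_s <= self.duration_s):
            raise ConfigError(
                "anesthesia_start_s/anesthesia_end_s must satisfy "
                f"0 <= start < end <= duration_s; got [{self.anesthesia_start_s}, "
                f"{self.anesthesia_end_s}] in {self.duration_s}"
            )
        if self.duration_law not in ("exponential", "gamma"):
            raise ConfigError(f"duration_law must be exponential or gamma, got {self.duration_law!r}")
        if self.duration_law == "gamma" and self.gamma_shape <= 0:
            raise ConfigError(f"gamma_shape must be positive, got {self.gamma_shape}")
        if set(self.band_weights) != set(DEFAULT_BANDS):
            raise ConfigError(
                f"band_weights must cover exactly {sorted(DEFAULT_BANDS)}, "
                f"got {sorted(self.band_weights)}"
            )
        if any(w < 0 for w in self.band_weights.values()):
            raise ConfigError("band_weights must be nonnegative")
        if abs(sum(self.band_weights.values()) - 1.0) > 1e-9:
            raise ConfigError(
                f"band_weights must sum to 1 within 1e-9, got {sum(self.band_weights.values())}"
            )
        if not (0 < self.sigma_suppression_uv < 5.0):
            raise ConfigError(
                "sigma_suppression_uv must lie in (0, 5) uV so suppression stays "
                f"within +/-15 uV (3-sigma), got {self.sigma_suppression_uv}"
            )
        if self.transition_ramp_s < 0:
            raise ConfigError(f"transition_ramp_s must be >= 0, got {self.transition_ramp_s}")


@dataclass(frozen=True)
class PhotometrySimConfig:
    """Generative specification for one ATP-sensor photometry trace.

    The during-anesthesia decline follows the saturating ramp
    ``s(t) = 1 - exp(-(t - onset)/tau)`` for ``t >= onset`` (0 before), and
    ``F(t) = f0 * (1 - decline_fraction * s(t)) - bleach_slope * t + noise``.
    """

    seed: int
    duration_s: float = 1500.0
    fs_hz: float = 100.0
    anesthesia_start_s: float = 200.0
    anesthesia_end_s: float = 1400.0
    f0_au: float = 100.0
    decline_fraction: float = 0.0
    decline_onset_s: float | None = None  # default: anesthesia onset
    decline_tau_s: float = 100.0
    bleach_slope_au_per_s: float = 0.0
    noise_sd_au: float = 0.0

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise ConfigError(f"fs_hz must be positive, got {self.fs_hz}")
        if self.duration_s <= 0:
            raise ConfigError(f"duration_s must be positive, got {self.duration_s}")
        if self.f0_au <= 0:
            raise ConfigError(f"f0_au must be positive, got {self.f0_au}")
        if not (0 <= self.decline_fraction < 1):
            raise ConfigError(
                f"decline_fraction must be in [0, 1), got {self.decline_fraction}"
            )
        if self.decline_tau_s <= 0:
            raise ConfigError(f"decline_tau_s must be positive, got {self.decline_tau_s}")
        if self.noise_sd_au < 0:
            raise ConfigError(f"noise_sd_au must be >= 0, got {self.noise_sd_au}")


@dataclass
class GroundTruth:
    """Per-sample labels and exact generative quantities for one subject."""

    state_labels: np.ndarray | None = None       # int8 per sample (EEG)
    true_bsr_percent: float | None = None        # over the anesthesia window
    true_suppression_time_s: float | None = None
    photometry_true_decline: float | None = None

    def labels_rle(self) -> list[list[int]]:
        """Run-length encoding [[label, count], ...] of the state labels."""
        x = self.state_labels
        if x is None:
            return []
        change = np.flatnonzero(np.diff(x)) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [x.size]))
        return [[int(x[a]), int(b - a)] for a, b in zip(starts, stops)]


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _draw_state_durations(cfg: BSSimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Alternating (state, duration) sequence filling the anesthesia window.

    Starts in the burst state at anesthesia onset; the final state is
    truncated at anesthesia end.  Returns (states, durations).
    """
    window = cfg.anesthesia_end_s - cfg.anesthesia_start_s
    states, durs = [], []
    total = 0.0
    state = LABEL_BURST
    mean = {LABEL_BURST: cfg.mean_burst_s, LABEL_SUPPRESSION: cfg.mean_suppression_s}
    while total < window:
        if cfg.duration_law == "exponential":
            d = rng.exponential(mean[state])
        else:
            d = rng.gamma(cfg.gamma_shape, mean[state] / cfg.gamma_shape)
        d = min(d, window - total)
        states.append(state)
        durs.append(d)
        total += d
        state = LABEL_SUPPRESSION if state == LABEL_BURST else LABEL_BURST
    return np.array(states, dtype=np.int8), np.array(durs)


def _labels_from_durations(cfg: BSSimConfig, states: np.ndarray, durs: np.ndarray) -> np.ndarray:
    n = int(round(cfg.duration_s * cfg.fs_hz))
    labels = np.full(n, LABEL_AWAKE, dtype=np.int8)
    fs = cfg.fs_hz
    edges = cfg.anesthesia_start_s + np.concatenate(([0.0], np.cumsum(durs)))
    idx = np.clip(np.round(edges * fs).astype(int), 0, n)
    for s, a, b in zip(states, idx[:-1], idx[1:]):
        labels[a:b] = s
    return labels


def _band_colored_noise(cfg: BSSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise whose power splits across the four bands per band_weights."""
    out = np.zeros(n)
    for name, (lo, hi) in DEFAULT_BANDS.items():
        w = cfg.band_weights[name]
        white = rng.standard_normal(n)
        if w == 0:
            continue
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=cfg.fs_hz, output="sos")
        comp = sps.sosfiltfilt(sos, white)
        comp_rms = np.sqrt(np.mean(comp**2))
        out += comp * (np.sqrt(w) / comp_rms)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _smooth_steps(x: np.ndarray, ramp_samples: int) -> np.ndarray:
    """Raised-cosine smoothing of a piecewise-constant array: each step
    becomes an S-ramp of ``ramp_samples`` width centered on the boundary."""
    if ramp_samples < 2:
        return x
    kernel = np.hanning(ramp_samples + 2)[1:-1]
    kernel /= kernel.sum()
    padded = np.concatenate(
        (np.full(ramp_samples, x[0]), x, np.full(ramp_samples, x[-1]))
    )
    y = np.convolve(padded, kernel, mode="same")
    return y[ramp_samples:-ramp_samples]


def simulate_bs_eeg(cfg: BSSimConfig) -> tuple[EEGRecording, GroundTruth]:
    """Generate one burst-suppression EEG recording plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))

    states, durs = _draw_state_durations(cfg, rng)
    labels = _labels_from_durations(cfg, states, durs)

    # target amplitude of the colored (band-weighted) component per sample
    amp = np.where(
        labels == LABEL_AWAKE,
        cfg.pre_anesthesia_rms_uv,
        np.where(labels == LABEL_BURST, cfg.burst_rms_uv, 0.0),
    ).astype(float)
    # suppression-floor white-noise SD per sample
    floor_sd = np.where(labels == LABEL_SUPPRESSION, cfg.sigma_suppression_uv, 0.0).astype(float)

    ramp_samples = int(round(cfg.transition_ramp_s * cfg.fs_hz))
    amp = _smooth_steps(amp, ramp_samples)
    floor_sd = _smooth_steps(floor_sd, ramp_samples)

    colored = _band_colored_noise(cfg, n, rng)
    white = rng.standard_normal(n)
    samples = amp * colored + floor_sd * white

    rec = EEGRecording(
        samples_uv=samples,
        fs_hz=cfg.fs_hz,
        anesthesia_start_s=cfg.anesthesia_start_s,
        anesthesia_end_s=cfg.anesthesia_end_s,
    )
    i0 = int(round(cfg.anesthesia_start_s * cfg.fs_hz))
    i1 = int(round(cfg.anesthesia_end_s * cfg.fs_hz))
    supp = int(np.sum(labels[i0:i1] == LABEL_SUPPRESSION))
    truth = GroundTruth(
        state_labels=labels,
        true_bsr_percent=100.0 * supp / (i1 - i0),
        true_suppression_time_s=supp / cfg.fs_hz,
    )
    return rec, truth


def ground_truth_bsr(cfg: BSSimConfig) -> float:
    """Ground-truth BSR (%) from the state-duration sequence alone.

    Draws exactly the same renewal sequence as :func:`simulate_bs_eeg` (same
    seed, same stream position) but skips signal synthesis; used for large
    replicate counts where only the BSR matters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    states, durs = _draw_state_durations(cfg, rng)
    window = cfg.anesthesia_end_s - cfg.anesthesia_start_s
    return 100.0 * float(durs[states == LABEL_SUPPRESSION].sum()) / window


# ---------------------------------------------------------------------------
# photometry synthesis
# ---------------------------------------------------------------------------

def simulate_photometry(cfg: PhotometrySimConfig) -> tuple[PhotometryTrace, GroundTruth]:
    """Generate one fluorescence trace plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    onset = cfg.decline_onset_s if cfg.decline_onset_s is not None else cfg.anesthesia_start_s
    s = np.where(t >= onset, 1.0 - np.exp(-np.maximum(t - onset, 0.0) / cfg.decline_tau_s), 0.0)
    f = cfg.f0_au * (1.0 - cfg.decline_fraction * s) - cfg.bleach_slope_au_per_s * t
    if cfg.noise_sd_au > 0:
        f = f + cfg.noise_sd_au * rng.standard_normal(n)
    trace = PhotometryTrace(
        f_au=f,
        fs_hz=cfg.fs_hz,
        anesthesia_start_s=cfg.anesthesia_start_s,
        anesthesia_end_s=cfg.anesthesia_end_s,
    )
    return trace, GroundTruth(photometry_true_decline=cfg.decline_fraction)


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

def young_eeg_preset(seed: int = 0, **overrides) -> BSSimConfig:
    """Light burst suppression (target BSR 20%), beta/alpha-tilted bursts."""
    base = dict(
        seed=seed,
        mean_suppression_s=2.0,
        mean_burst_s=8.0,
        duration_law="gamma",
        gamma_shape=2.0,
        band_weights={"delta": 0.25, "theta": 0.20, "alpha": 0.25, "beta": 0.30},
    )
    base.update(overrides)
    return BSSimConfig(**base)


def aged_eeg_preset(seed: int = 0, **overrides) -> BSSimConfig:
    """Deep burst suppression (target BSR 60%), delta-dominant bursts."""
    base = dict(
        seed=seed,
        mean_suppression_s=4.5,
        mean_burst_s=3.0,
        duration_law="gamma",
        gamma_shape=2.0,
        band_weights={"delta": 0.55, "theta": 0.20, "alpha": 0.15, "beta": 0.10},
    )
    base.update(overrides)
    return BSSimConfig(**base)


def young_photometry_preset(seed: int = 0, **overrides) -> PhotometrySimConfig:
    """Stable ATP signal through anesthesia (no decline)."""
    base = dict(seed=seed, decline_fraction=0.0, noise_sd_au=0.3,
                bleach_slope_au_per_s=0.002)
    base.update(overrides)
    return PhotometrySimConfig(**base)


def aged_photometry_preset(seed: int = 0, **overrides) -> PhotometrySimConfig:
    """ATP signal declining ~20% after anesthesia onset (tau 100 s)."""
    base = dict(seed=seed, decline_fraction=0.2, decline_tau_s=100.0,
                noise_sd_au=0.3, bleach_slope_au_per_s=0.002)
    base.update(overrides)
    return PhotometrySimConfig(**base)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: EEG/photometry presets plus scalar-assay parameters.

    Scalar assays are phenomenological per-subject draws: emergence time is
    lognormal(mu, sigma) seconds; qPCR dCt (target - reference Ct) is normal;
    densitometry target/control ratio is normal (control lane intensity
    lognormal around 1e4 a.u.); tissue ATP content is normal (a.u.).
    """

    label: str
    n_subjects: int
    eeg: BSSimConfig
    phot: PhotometrySimConfig
    emergence_mu_log: float
    emergence_sigma_log: float
    qpcr_dct_mean: float = 5.0
    qpcr_dct_sd: float = 0.25
    ct_reference_mean: float = 17.0
    ct_reference_sd: float = 0.3
    densitometry_ratio_mean: float = 1.0
    densitometry_ratio_sd: float = 0.1
    atp_mean: float = 6.0
    atp_sd: float = 0.5

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        self.eeg.validate()
        self.phot.validate()


@dataclass(frozen=True)
class CohortSpec:
    """A seeded multi-group cohort; per-subject seeds are derived as
    ``seed + 10000 * (group_index + 1) + subject_index`` and recorded in the
    manifest for exact replay."""

    seed: int
    groups: tuple[GroupSpec, ...]

    def validate(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"group labels must be unique, got {labels}")
        for g in self.groups:
            g.validate()

    def subject_seed(self, group_index: int, subject_index: int) -> int:
        return int(self.seed + 10_000 * (group_index + 1) + subject_index)


def young_group_preset(n_subjects: int = 4, label: str = "young") -> GroupSpec:
    return GroupSpec(
        label=label,
        n_subjects=n_subjects,
        eeg=young_eeg_preset(),
        phot=young_photometry_preset(),
        emergence_mu_log=float(np.log(100.0)),
        emergence_sigma_log=0.25,
        qpcr_dct_mean=5.0,
        densitometry_ratio_mean=1.0,
        atp_mean=6.0,
    )


def aged_group_preset(n_subjects: int = 4, label: str = "aged") -> GroupSpec:
    return GroupSpec(
        label=label,
        n_subjects=n_subjects,
        eeg=aged_eeg_preset(),
        phot=aged_photometry_preset(),
        emergence_mu_log=float(np.log(250.0)),
        emergence_sigma_log=0.25,
        qpcr_dct_mean=6.0,           # one cycle above control => expression ~0.5
        densitometry_ratio_mean=0.5,
        atp_mean=4.0,
    )


def demo_cohort_spec(seed: int = 0, n_per_group: int = 4) -> CohortSpec:
    """The standard young-vs-aged demo cohort."""
    return CohortSpec(
        seed=seed,
        groups=(young_group_preset(n_per_group), aged_group_preset(n_per_group)),
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, np.floating):
            d[k] = float(v)
    return d


def simulate_subject(
    spec: CohortSpec, group_index: int, subject_index: int
) -> dict:
    """Generate all modalities for one subject, in memory.

    Returns a dict with keys ``subject_id, group_label, eeg, eeg_truth,
    phot, phot_truth, emergence_s, ct_target, ct_reference,
    intensity_target, intensity_control, atp_au, seed``.
    """
    g = spec.groups[group_index]
    seed = spec.subject_seed(group_index, subject_index)
    subject_id = f"{g.label}_{subject_index + 1:02d}"

    eeg_cfg = dataclasses.replace(g.eeg, seed=seed)
    rec, eeg_truth = simulate_bs_eeg(eeg_cfg)
    rec.subject_id = subject_id
    rec.group_label = g.label

    phot_cfg = dataclasses.replace(g.phot, seed=seed + 500_000)
    trace, phot_truth = simulate_photometry(phot_cfg)
    trace.subject_id = subject_id
    trace.group_label = g.label

    rng = np.random.default_rng(seed + 900_000)
    emergence = float(rng.lognormal(g.emergence_mu_log, g.emergence_sigma_log))
    dct = rng.normal(g.qpcr_dct_mean, g.qpcr_dct_sd)
    ct_ref = rng.normal(g.ct_reference_mean, g.ct_reference_sd)
    ratio = max(1e-3, rng.normal(g.densitometry_ratio_mean, g.densitometry_ratio_sd))
    control_int = float(np.exp(rng.normal(np.log(1e4), 0.1)))
    atp = float(rng.normal(g.atp_mean, g.atp_sd))

    return {
        "subject_id": subject_id,
        "group_label": g.label,
        "seed": seed,
        "eeg": rec,
        "eeg_truth": eeg_truth,
        "phot": trace,
        "phot_truth": phot_truth,
        "emergence_s": emergence,
        "ct_target": float(ct_ref + dct),
        "ct_reference": float(ct_ref),
        "intensity_target": float(ratio * control_int),
        "intensity_control": control_int,
        "atp_au": atp,
    }


def iter_subjects(spec: CohortSpec):
    """Yield :func:`simulate_subject` dicts for every subject in the cohort."""
    spec.validate()
    for gi, g in enumerate(spec.groups):
        for si in range(g.n_subjects):
            yield simulate_subject(spec, gi, si)


def simulate_cohort(spec: CohortSpec, out_dir, eeg_format: str = "tsv") -> dict:
    """Write a full synthetic cohort to ``out_dir`` and return the manifest.

    Per subject: an EEG file (TSV or EDF) with annotation sidecar, a
    photometry TSV with sidecar, and a ground-truth JSON (run-length-encoded
    state labels plus exact BSR / suppression time / decline).  Cohort-level:
    ``emergence_times.tsv``, ``qpcr.tsv``, ``densitometry.tsv``, ``atp.tsv``
    and ``manifest.json`` listing every file, seed and preset.  Re-running
    with the same spec reproduces identical files.
    """
    import pandas as pd

    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"tsv": ".tsv", "edf": ".edf"}[eeg_format]

    manifest: dict = {
        "cohort_seed": spec.seed,
        "eeg_format": eeg_format,
        "groups": [],
        "files": {"eeg": [], "photometry": [], "ground_truth": [], "tables": []},
    }
    rows_beh, rows_qpcr, rows_dens, rows_atp = [], [], [], []

    for gi, g in enumerate(spec.groups):
        manifest["groups"].append(
            {
                "label": g.label,
                "n_subjects": g.n_subjects,
                "eeg_preset": _config_dict(g.eeg),
                "photometry_preset": _config_dict(g.phot),
                "subject_seeds": [spec.subject_seed(gi, si) for si in range(g.n_subjects)],
            }
        )
        for si in range(g.n_subjects):
            sub = simulate_subject(spec, gi, si)
            sid = sub["subject_id"]

            eeg_path = out / f"{sid}_eeg{ext}"
            write_eeg(sub["eeg"], eeg_path, fmt=eeg_format)
            manifest["files"]["eeg"].append(eeg_path.name)

            phot_path = out / f"{sid}_photometry.tsv"
            write_photometry(sub["phot"], phot_path)
            manifest["files"]["photometry"].append(phot_path.name)

            gt_path = out / f"{sid}_ground_truth.json"
            truth = sub["eeg_truth"]
            gt_path.write_text(
                json.dumps(
                    {
                        "subject_id": sid,
                        "label_names": {str(k): v for k, v in LABEL_NAMES.items()},
                        "state_labels_rle": truth.labels_rle(),
                        "true_bsr_percent": truth.true_bsr_percent,
                        "true_suppression_time_s": truth.true_suppression_time_s,
                        "photometry_true_decline": sub["phot_truth"].photometry_true_decline,
                    }
                )
                + "\n"
            )
            manifest["files"]["ground_truth"].append(gt_path.name)

            base = {"subject_id": sid, "group_label": g.label}
            rows_beh.append({**base, "rrr_time_s": sub["emergence_s"]})
            rows_qpcr.append(
                {**base, "ct_target": sub["ct_target"], "ct_reference": sub["ct_reference"]}
            )
            rows_dens.append(
                {
                    **base,
                    "intensity_target": sub["intensity_target"],
                    "intensity_control": sub["intensity_control"],
                }
            )
            rows_atp.append({**base, "atp_au": sub["atp_au"]})

    for name, rows in [
        ("emergence_times.tsv", rows_beh),
        ("qpcr.tsv", rows_qpcr),
        ("densitometry.tsv", rows_dens),
        ("atp.tsv", rows_atp),
    ]:
        pd.DataFrame(rows).to_csv(out / name, sep="\t", index=False, float_format="%.9g")
        manifest["files"]["tables"].append(name)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
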