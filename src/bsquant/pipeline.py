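"""End-to-end orchestration: simulate -> filter -> detect -> spectral ->
photometry -> molecular -> statistics, with a machine-readable manifest.

A run is driven by a :class:`RunConfig` (JSON-compatible) and a master
seed; every per-subject seed is derived deterministically from the master
seed and recorded, so an identical config + seed reproduces byte-identical
numeric outputs.  Outputs per run directory:

* ``cohort/`` — the simulated input data (EEG, photometry, ground truth,
  scalar tables, cohort manifest);
* ``events/<subject>_events.tsv`` — detected suppression events;
* ``suppression_summary.tsv`` — per-subject cumulative suppression time,
  BSR, event count (plus ground truth where available);
* ``band_power.tsv`` — per-subject relative band power;
* ``photometry_dff/<subject>_dff.tsv`` + ``photometry_summary.tsv``;
* ``group_dff/<group>.tsv`` — aligned group-mean dF/F traces with SEM;
* ``molecular.tsv`` — qPCR relative expression and densitometry ratios;
* ``measures.tsv`` — the long-form per-subject measure table;
* ``comparisons.tsv`` — the statistical decision trail per measure;
* ``run_manifest.json`` — config, config hash, seeds, artifact list.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sim_cohort
from .eeg_io import read_eeg, read_photometry
from .group_stats import figure_table
from .molecular_quant import ddct_relative_expression, normalize_densitometry
from .photometry import compute_dff, epoch_change, group_mean_trace
from .spectral_metrics import relative_band_power
from .suppression_metrics import detect_suppressions, summarize_suppression

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]

logger = logging.getLogger("bsquant.pipeline")

_FLOAT_FMT = "%.9g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (all defaults mirror the study
    parameters: 250 Hz EEG, 0.5-70 Hz band, +/-15 uV / 0.2 s suppression
    rule, 100-s photometry baseline, 20-min anesthesia window)."""

    seed: int = 0
    out_dir: str = "bsquant_run"
    n_per_group: int = 4
    eeg_format: str = "tsv"            # tsv | edf
    threshold_uv: float = 15.0
    min_duration_s: float = 0.2
    filter_low_hz: float = 0.5
    filter_high_hz: float = 70.0
    detect_on_filtered: bool = True
    baseline_s: float = 100.0
    control_group: str = "young"
    stats_design: str = "auto"         # auto | one_way

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def validate_config(config: RunConfig | dict) -> list[str]:
    """Return a list of findings (field path + problem); empty iff runnable."""
    if isinstance(config, dict):
        try:
            config = RunConfig.from_dict(config)
        except (TypeError, ValueError) as exc:
            return [f"config: {exc}"]
    findings = []
    if config.n_per_group < 1:
        findings.append(f"n_per_group: must be >= 1, got {config.n_per_group}")
    if config.eeg_format not in ("tsv", "edf"):
        findings.append(f"eeg_format: must be tsv or edf, got {config.eeg_format!r}")
    if config.threshold_uv <= 0:
        findings.append(f"detection.threshold_uv: must be positive, got {config.threshold_uv}")
    if config.min_duration_s < 0:
        findings.append(f"detection.min_duration_s: must be >= 0, got {config.min_duration_s}")
    if not (0 < config.filter_low_hz < config.filter_high_hz):
        findings.append(
            "filter: must satisfy 0 < filter_low_hz < filter_high_hz, got "
            f"[{config.filter_low_hz}, {config.filter_high_hz}]"
        )
    if config.baseline_s <= 0:
        findings.append(f"photometry.baseline_s: must be positive, got {config.baseline_s}")
    if config.stats_design not in ("auto", "one_way"):
        findings.append(f"stats_design: must be auto or one_way, got {config.stats_design!r}")
    try:
        spec = sim_cohort.demo_cohort_spec(config.seed, max(1, config.n_per_group))
        spec.validate()
        for g in spec.groups:
            if g.eeg.anesthesia_end_s < g.eeg.anesthesia_start_s:
                findings.append(f"{g.label}.eeg.anesthesia: end before start")
    except sim_cohort.ConfigError as exc:
        findings.append(f"cohort: {exc}")
    return findings


def _stage(name: str):
    """Decorator-free stage guard: context manager logging one structured line."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage=%s status=failed elapsed_s=%.2f error=%s", name, dt, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage=%s status=ok elapsed_s=%.2f", name, dt)
            return False

    return _Ctx()


def run_pipeline(
    config: RunConfig, cohort_spec: sim_cohort.CohortSpec | None = None
) -> dict:
    """Execute the full analysis and return the run manifest.

    ``cohort_spec`` overrides the default young-vs-aged demo cohort (its
    seed is replaced by ``config.seed``).
    """
    findings = validate_config(config)
    if findings:
        raise PipelineError("invalid config: " + "; ".join(findings))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "events").mkdir(exist_ok=True)
    (out / "photometry_dff").mkdir(exist_ok=True)
    (out / "group_dff").mkdir(exist_ok=True)

    if cohort_spec is None:
        cohort_spec = sim_cohort.demo_cohort_spec(config.seed, config.n_per_group)
    else:
        cohort_spec = dataclasses.replace(cohort_spec, seed=config.seed)

    with _stage("simulate"):
        cohort_dir = out / "cohort"
        cohort_manifest = sim_cohort.simulate_cohort(
            cohort_spec, cohort_dir, eeg_format=config.eeg_format
        )

    filter_band = (
        (config.filter_low_hz, config.filter_high_hz) if config.detect_on_filtered else None
    )
    supp_rows, band_rows, measure_rows = [], [], []
    with _stage("detect+spectral"):
        truth_by_subject = {}
        for gt_name in cohort_manifest["files"]["ground_truth"]:
            gt = json.loads((cohort_dir / gt_name).read_text())
            truth_by_subject[gt["subject_id"]] = gt
        for eeg_name in cohort_manifest["files"]["eeg"]:
            rec = read_eeg(cohort_dir / eeg_name)
            sid = eeg_name.replace("_eeg", "").rsplit(".", 1)[0]
            rec.subject_id = sid
            group = sid.rsplit("_", 1)[0]
            events = detect_suppressions(
                rec,
                threshold_uv=config.threshold_uv,
                min_duration_s=config.min_duration_s,
                filter_band=filter_band,
            )
            pd.DataFrame(
                [
                    {
                        "subject_id": sid,
                        "onset_s": ev.onset_s,
                        "offset_s": ev.offset_s,
                        "duration_s": ev.duration_s,
                    }
                    for ev in events
                ]
            ).to_csv(out / "events" / f"{sid}_events.tsv", sep="\t", index=False,
                     float_format="%.6f")
            summ = summarize_suppression(events, rec.anesthesia_window)
            gt = truth_by_subject.get(sid, {})
            supp_rows.append(
                {
                    "subject_id": sid,
                    "group_label": group,
                    "suppression_time_s": summ.total_suppression_time_s,
                    "bsr_percent": summ.bsr_percent,
                    "n_events": summ.n_events,
                    "true_bsr_percent": gt.get("true_bsr_percent", np.nan),
                    "true_suppression_time_s": gt.get("true_suppression_time_s", np.nan),
                }
            )
            bp = relative_band_power(rec)
            for band, frac in bp.relative_power.items():
                band_rows.append(
                    {"subject_id": sid, "group_label": group, "band": band, "rel_power": frac}
                )
            measure_rows += [
                {"subject_id": sid, "group_label": group, "measure": "suppression_time_s",
                 "value": summ.total_suppression_time_s},
                {"subject_id": sid, "group_label": group, "measure": "bsr_percent",
                 "value": summ.bsr_percent},
            ] + [
                {"subject_id": sid, "group_label": group,
                 "measure": f"rel_power_{band}", "value": frac}
                for band, frac in bp.relative_power.items()
            ]

    phot_rows = []
    with _stage("photometry"):
        dffs_by_group: dict[str, list] = {}
        for phot_name in cohort_manifest["files"]["photometry"]:
            trace = read_photometry(cohort_dir / phot_name)
            sid = phot_name.replace("_photometry", "").rsplit(".", 1)[0]
            group = sid.rsplit("_", 1)[0]
            end = trace.anesthesia_start_s
            dff = compute_dff(trace, (max(0.0, end - config.baseline_s), end))
            dff.subject_id = sid
            dffs_by_group.setdefault(group, []).append(dff)
            ch = epoch_change(dff)
            phot_rows.append(
                {
                    "subject_id": sid,
                    "group_label": group,
                    "f0_au": dff.f0_au,
                    "pre_mean_dff": ch.pre_mean,
                    "during_mean_dff": ch.during_mean,
                    "dff_change": ch.change,
                }
            )
            pd.DataFrame({"time_s": dff.times_s, "dff": dff.dff}).to_csv(
                out / "photometry_dff" / f"{sid}_dff.tsv", sep="\t", index=False,
                float_format=_FLOAT_FMT,
            )
            measure_rows.append(
                {"subject_id": sid, "group_label": group, "measure": "dff_change",
                 "value": ch.change}
            )
        for group, dffs in dffs_by_group.items():
            if len(dffs) >= 2:
                gm = group_mean_trace(dffs)
                pd.DataFrame(
                    {"time_s": gm.times_s, "mean_dff": gm.mean, "sem_dff": gm.sem}
                ).to_csv(out / "group_dff" / f"{group}.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)

    with _stage("molecular"):
        qpcr = pd.read_csv(cohort_dir / "qpcr.tsv", sep="\t")
        control = config.control_group
        if control not in set(qpcr["group_label"]):
            control = qpcr["group_label"].iloc[0]
        qpcr_out = ddct_relative_expression(qpcr, control_group=control)
        dens = normalize_densitometry(pd.read_csv(cohort_dir / "densitometry.tsv", sep="\t"))
        molecular = qpcr_out.merge(
            dens[["subject_id", "norm_ratio"]], on="subject_id", how="outer"
        )
        molecular.to_csv(out / "molecular.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        emergence = pd.read_csv(cohort_dir / "emergence_times.tsv", sep="\t")
        atp = pd.read_csv(cohort_dir / "atp.tsv", sep="\t")
        for df, col, measure in [
            (qpcr_out, "rel_expression", "rel_expression"),
            (dens, "norm_ratio", "densitometry_ratio"),
            (emergence, "rrr_time_s", "emergence_time_s"),
            (atp, "atp_au", "atp_au"),
        ]:
            measure_rows += [
                {"subject_id": r["subject_id"], "group_label": r["group_label"],
                 "measure": measure, "value": r[col]}
                for _, r in df.iterrows()
            ]

    with _stage("stats"):
        measures = pd.DataFrame(measure_rows)
        measures.to_csv(out / "measures.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        results, table = figure_table(measures)
        table.to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(supp_rows).to_csv(
        out / "suppression_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(band_rows).to_csv(
        out / "band_power.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(phot_rows).to_csv(
        out / "photometry_summary.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    artifacts = sorted(
        str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        and p.name != "run_manifest.json"
    )
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "cohort_seed": cohort_spec.seed,
        "subject_seeds": {
            g["label"]: g["subject_seeds"] for g in cohort_manifest["groups"]
        },
        "artifacts": artifacts,
        "n_comparisons": len(results),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
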