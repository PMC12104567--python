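"""Scalar molecular quantification: 2^-ddCt expression and densitometry.

qPCR relative expression uses the comparative-Ct method: each sample's
target Ct is normalized to its reference-gene Ct (dCt), re-baselined to the
control group's mean dCt (ddCt), and exponentiated, expression = 2^-ddCt.
With the group-mean baseline the control group's *geometric* mean
expression is exactly 1.  Densitometry records are normalized as the plain
ratio target/internal-control per lane.  Behavioral emergence
(righting-reflex recovery) times are carried as plain per-subject scalars.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ddct_relative_expression",
    "normalize_densitometry",
]

_QPCR_COLS = ("subject_id", "group_label", "ct_target", "ct_reference")
_DENS_COLS = ("subject_id", "group_label", "intensity_target", "intensity_control")


def ddct_relative_expression(
    samples: pd.DataFrame, control_group: str, baseline: str = "group_mean"
) -> pd.DataFrame:
    """Per-sample relative expression by the 2^-ddCt method.

    Parameters
    ----------
    samples
        Table with columns ``subject_id, group_label, ct_target, ct_reference``.
    control_group
        The calibrator group label; its mean dCt is the ddCt baseline.
    baseline
        ``"group_mean"`` (default): ddCt_i = dCt_i - mean(dCt | control).
        ``"paired"``: samples are paired to control samples by ``subject_id``
        and each pair uses its own control dCt.

    Returns the input with ``dct``, ``ddct`` and ``rel_expression`` columns
    added; ``log2(rel_expression) == -ddct`` exactly.
    """
    missing = [c for c in _QPCR_COLS if c not in samples.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns {missing}")
    df = samples.copy()
    ct = df[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("Ct values must be finite")
    if ((ct < 5) | (ct > 40)).any():
        warnings.warn("Ct values outside the typical 5-40 cycle range", stacklevel=2)
    df["dct"] = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    control = df[df["group_label"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} absent from table")
    if baseline == "group_mean":
        df["ddct"] = df["dct"] - control["dct"].mean()
    elif baseline == "paired":
        ref = control.set_index("subject_id")["dct"]
        if ref.index.duplicated().any():
            raise ValueError("paired baseline needs unique control subject_ids")
        pair_dct = df["subject_id"].map(ref)
        if pair_dct.isna().any():
            raise ValueError("paired baseline: some subjects lack a control pair")
        df["ddct"] = df["dct"] - pair_dct
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    df["rel_expression"] = 2.0 ** (-df["ddct"])
    return df


def normalize_densitometry(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize band densities to the lane's internal control.

    Adds ``norm_ratio = intensity_target / intensity_control``; intensities
    must be strictly positive.
    """
    missing = [c for c in _DENS_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"densitometry table missing columns {missing}")
    df = records.copy()
    it = df["intensity_target"].to_numpy(dtype=float)
    ic = df["intensity_control"].to_numpy(dtype=float)
    if not (np.all(it > 0) and np.all(ic > 0)):
        raise ValueError("densitometry intensities must be strictly positive")
    df["norm_ratio"] = it / ic
    return df
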