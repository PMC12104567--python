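"""ATP-sensor dF/F: baseline normalization and pre/during-anesthesia change.

F0 is the mean fluorescence over the 100 s preceding anesthesia onset;
dF/F = (F - F0)/F0.  Per subject the change in mean dF/F between the
baseline window and the anesthesia window is reported, and per group an
onset-aligned mean trace with SEM is written.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bsquant.eeg_io import read_photometry
from bsquant.photometry import compute_dff, epoch_change, group_mean_trace

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    manifest = json.loads((COHORT_DIR / "manifest.json").read_text())
    rows, by_group = [], {}
    for name in manifest["files"]["photometry"]:
        trace = read_photometry(COHORT_DIR / name)
        sid = name.replace("_photometry.tsv", "")
        dff = compute_dff(trace)
        by_group.setdefault(sid.rsplit("_", 1)[0], []).append(dff)
        ch = epoch_change(dff)
        rows.append({"subject_id": sid, "group_label": sid.rsplit("_", 1)[0],
                     "f0_au": dff.f0_au, "pre_mean_dff": ch.pre_mean,
                     "during_mean_dff": ch.during_mean, "dff_change": ch.change})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "photometry_summary.tsv", sep="\t", index=False,
              float_format="%.6g")
    for group, dffs in by_group.items():
        gm = group_mean_trace(dffs)
        pd.DataFrame({"time_s": gm.times_s, "mean_dff": gm.mean, "sem_dff": gm.sem}).to_csv(
            RESULTS / f"group_dff_{group}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    print(df.groupby("group_label")["dff_change"].agg(["mean", "sem"]).round(4).to_string())


if __name__ == "__main__":
    main()
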