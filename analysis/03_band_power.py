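"""Relative EEG band power (delta/theta/alpha/beta) during anesthesia.

Welch PSD (2-s Hamming segments, 50% overlap) over the anesthesia window;
each band's power as a fraction of total power over 0.5-25 Hz.  The aged
preset generates delta-dominant bursts, the young preset a beta/alpha tilt,
so group-mean delta fractions should separate clearly.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bsquant.eeg_io import read_eeg
from bsquant.spectral_metrics import relative_band_power

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    manifest = json.loads((COHORT_DIR / "manifest.json").read_text())
    rows = []
    for eeg_name in manifest["files"]["eeg"]:
        rec = read_eeg(COHORT_DIR / eeg_name)
        sid = eeg_name.replace("_eeg.tsv", "")
        bp = relative_band_power(rec)
        for band, frac in bp.relative_power.items():
            rows.append({"subject_id": sid, "group_label": sid.rsplit("_", 1)[0],
                         "band": band, "rel_power": frac})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "band_power.tsv", sep="\t", index=False, float_format="%.6g")
    print(df.pivot_table(index="group_label", columns="band",
                         values="rel_power").round(3).to_string())


if __name__ == "__main__":
    main()
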