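"""Generate the synthetic young-vs-aged cohort that drives the analysis.

Two groups of four mice: 25-min recordings with a 20-min anesthesia window
(200-1400 s), EEG at 250 Hz, ATP photometry at 100 Hz, plus emergence
times, qPCR Ct values, densitometry and a tissue-ATP scalar per subject.
The aged preset targets a 60% burst-suppression ratio with delta-dominant
bursts and a declining ATP signal; the young preset targets 20% with a
flat ATP signal.  All data land under scratch/cohort with a manifest.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bsquant.sim_cohort import demo_cohort_spec, simulate_cohort

COHORT_DIR = Path(__file__).resolve().parents[1] / "scratch" / "cohort"
SEED = 0


def main() -> None:
    spec = demo_cohort_spec(seed=SEED, n_per_group=4)
    manifest = simulate_cohort(spec, COHORT_DIR)
    print(f"cohort written to {COHORT_DIR} (seed {SEED})")
    for group in manifest["groups"]:
        bsrs = []
        for fname in manifest["files"]["ground_truth"]:
            gt = json.loads((COHORT_DIR / fname).read_text())
            if gt["subject_id"].startswith(group["label"]):
                bsrs.append(gt["true_bsr_percent"])
        mean = sum(bsrs) / len(bsrs)
        print(f"  {group['label']}: n={group['n_subjects']}, "
              f"ground-truth BSR mean {mean:.1f}%")


if __name__ == "__main__":
    main()
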