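"""Molecular quantification: 2^-ddCt relative expression and densitometry.

NDUFA10-like qPCR Ct values are normalized to the reference gene and to the
young (control) group; western-blot densities are normalized to each lane's
internal control.  The aged presets are generated one Ct cycle above
control (expression ~0.5) and at half the control density ratio.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bsquant.molecular_quant import ddct_relative_expression, normalize_densitometry

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    qpcr = ddct_relative_expression(
        pd.read_csv(COHORT_DIR / "qpcr.tsv", sep="\t"), control_group="young"
    )
    dens = normalize_densitometry(pd.read_csv(COHORT_DIR / "densitometry.tsv", sep="\t"))
    merged = qpcr.merge(dens[["subject_id", "norm_ratio"]], on="subject_id")
    merged.to_csv(RESULTS / "molecular.tsv", sep="\t", index=False, float_format="%.6g")
    print(merged.groupby("group_label")[["rel_expression", "norm_ratio"]]
          .mean().round(3).to_string())


if __name__ == "__main__":
    main()
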