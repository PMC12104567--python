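"""Group comparisons for every cohort measure via the normality-gated path.

Assembles the long-form measure table (suppression time, BSR, band
fractions, dF/F change, emergence time, tissue ATP, relative expression,
densitometry ratio) and runs, per measure, Shapiro-Wilk-gated Student t /
Mann-Whitney comparisons (two groups here; ANOVA + Tukey would engage with
three or more).  The decision trail per measure lands in
results/comparisons.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from bsquant.group_stats import figure_table

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []

    supp = pd.read_csv(RESULTS / "suppression_summary.tsv", sep="\t")
    for _, r in supp.iterrows():
        rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                         measure="suppression_time_s", value=r.suppression_time_s))
        rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                         measure="bsr_percent", value=r.bsr_percent))
    band = pd.read_csv(RESULTS / "band_power.tsv", sep="\t")
    for _, r in band.iterrows():
        rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                         measure=f"rel_power_{r.band}", value=r.rel_power))
    phot = pd.read_csv(RESULTS / "photometry_summary.tsv", sep="\t")
    for _, r in phot.iterrows():
        rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                         measure="dff_change", value=r.dff_change))
    mol = pd.read_csv(RESULTS / "molecular.tsv", sep="\t")
    for _, r in mol.iterrows():
        rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                         measure="rel_expression", value=r.rel_expression))
        rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                         measure="densitometry_ratio", value=r.norm_ratio))
    for fname, measure, col in [("emergence_times.tsv", "emergence_time_s", "rrr_time_s"),
                                ("atp.tsv", "atp_au", "atp_au")]:
        df = pd.read_csv(COHORT_DIR / fname, sep="\t")
        for _, r in df.iterrows():
            rows.append(dict(subject_id=r.subject_id, group_label=r.group_label,
                             measure=measure, value=r[col]))

    measures = pd.DataFrame(rows)
    measures.to_csv(RESULTS / "measures.tsv", sep="\t", index=False, float_format="%.6g")
    results, table = figure_table(measures)
    table.to_csv(RESULTS / "comparisons.tsv", sep="\t", index=False, float_format="%.6g")
    print(table[["measure", "test", "p_value"]].to_string(index=False))
    sig = [r.measure for r in results if r.significant]
    print(f"\nsignificant at 0.05: {', '.join(sig) if sig else 'none'}")


if __name__ == "__main__":
    main()
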