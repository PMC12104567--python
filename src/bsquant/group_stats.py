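"""Group-comparison statistics with a normality-gated decision path.

The decision path mirrors common practice in small-cohort physiology:

* two groups — Shapiro-Wilk normality per group (Lilliefors'
  Kolmogorov-Smirnov for n > 50); both normal at alpha 0.05 →
  two-sided unpaired Student t-test, otherwise two-sided Mann-Whitney U;
* three or more groups — one-way ANOVA (or two-way ANOVA on a full
  factorial) followed by Tukey's HSD multiple-comparison test at
  family-wise alpha 0.05.

Every result records the full decision trail (normality statistic and
p per group, chosen test, statistic, p, mean +/- SEM, n) so the choice is
auditable and reproducible.  All tests are two-sided; Welch's correction is
off by default (classic Student t) and available via ``welch=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "ComparisonResult",
    "compare_two_groups",
    "compare_many_groups",
    "figure_table",
]

NORMALITY_ALPHA = 0.05
SHAPIRO_MAX_N = 50


@dataclass
class ComparisonResult:
    measure: str
    groups: list[str]
    n_per_group: list[int]
    means: list[float]
    sems: list[float]
    normality_test: str
    normality_p: list[float]
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None  # Tukey table for >2 groups
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def to_row(self) -> dict:
        return {
            "measure": self.measure,
            "groups": "|".join(self.groups),
            "n": "|".join(str(n) for n in self.n_per_group),
            "means": "|".join(f"{m:.6g}" for m in self.means),
            "sems": "|".join(f"{s:.6g}" for s in self.sems),
            "normality_test": self.normality_test,
            "normality_p": "|".join(f"{p:.4g}" for p in self.normality_p),
            "test": self.test,
            "statistic": f"{self.statistic:.6g}" if np.isfinite(self.statistic) else "",
            "p_value": self.p_value,
        }


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    n = x.size
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return float(np.mean(x)), sem


def _normality(x: np.ndarray) -> tuple[str, float]:
    """Normality p-value; Shapiro-Wilk for n <= 50, Lilliefors KS above."""
    if np.ptp(x) == 0:
        # Degenerate sample: Shapiro-Wilk is undefined on constant data;
        # treat as non-normal so the rank path (which handles total ties)
        # is taken.
        return ("degenerate", 0.0)
    if x.size <= SHAPIRO_MAX_N:
        return ("shapiro", float(st.shapiro(x).pvalue))
    from statsmodels.stats.diagnostic import lilliefors

    return ("lilliefors_ks", float(lilliefors(x, dist="norm")[1]))


def compare_two_groups(
    x,
    y,
    labels: tuple[str, str] = ("group1", "group2"),
    measure: str = "",
    alpha_normality: float = NORMALITY_ALPHA,
    welch: bool = False,
) -> ComparisonResult:
    """Normality-gated two-group comparison (Student t or Mann-Whitney U)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError(f"need n >= 3 per group, got {x.size} and {y.size}")
    norm_name_x, p_x = _normality(x)
    norm_name_y, p_y = _normality(y)
    both_normal = (p_x > alpha_normality) and (p_y > alpha_normality)
    if both_normal:
        res = st.ttest_ind(x, y, equal_var=not welch)
        test = "welch_t" if welch else "student_t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if np.ptp(np.concatenate([x, y])) == 0:
            # All observations tied: zero rank separation, no evidence of a
            # shift (the tie-corrected U statistic is 0/0 here).
            test, stat, p = "mann_whitney", float(x.size * y.size / 2), 1.0
        else:
            res = st.mannwhitneyu(x, y, alternative="two-sided")
            test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    mx, sx = _mean_sem(x)
    my, sy = _mean_sem(y)
    return ComparisonResult(
        measure=measure,
        groups=list(labels),
        n_per_group=[x.size, y.size],
        means=[mx, my],
        sems=[sx, sy],
        normality_test="/".join(sorted({norm_name_x, norm_name_y})),
        normality_p=[p_x, p_y],
        test=test,
        statistic=stat,
        p_value=p,
    )


def _tukey_table(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
    return pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )


def compare_many_groups(
    groups: dict[str, np.ndarray] | pd.DataFrame,
    design: str = "one_way",
    factors: tuple[str, str] | None = None,
    measure: str = "",
) -> ComparisonResult:
    """ANOVA (one- or two-way) followed by Tukey's HSD pairwise table.

    ``groups`` is either a mapping label -> sample (one-way) or a long-form
    DataFrame with a ``value`` column plus factor columns (two-way; pass the
    two factor names via ``factors``, every cell of the factorial must be
    populated with n >= 2).
    """
    if design == "one_way":
        if isinstance(groups, pd.DataFrame):
            groups = {k: g["value"].to_numpy() for k, g in groups.groupby("group_label")}
        labels = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in labels]
        if len(labels) < 3:
            raise ValueError("one-way ANOVA needs >= 3 groups; use compare_two_groups")
        if any(s.size < 2 for s in samples):
            raise ValueError("each group needs n >= 2")
        f_res = st.f_oneway(*samples)
        values = np.concatenate(samples)
        value_labels = np.concatenate([[k] * s.size for k, s in zip(labels, samples)])
        pairwise = _tukey_table(values, value_labels)
        norm_ps = [_normality(s)[1] for s in samples]
        stats_pairs = [_mean_sem(s) for s in samples]
        return ComparisonResult(
            measure=measure,
            groups=labels,
            n_per_group=[s.size for s in samples],
            means=[m for m, _ in stats_pairs],
            sems=[s for _, s in stats_pairs],
            normality_test="shapiro",
            normality_p=norm_ps,
            test="one_way_anova+tukey",
            statistic=float(f_res.statistic),
            p_value=float(f_res.pvalue),
            pairwise=pairwise,
        )
    if design == "two_way":
        if not (isinstance(groups, pd.DataFrame) and factors and len(factors) == 2):
            raise ValueError("two-way design needs a DataFrame and two factor names")
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fa, fb = factors
        df = groups.rename(columns={fa: "_fa", fb: "_fb"}).copy()
        cells = df.groupby(["_fa", "_fb"]).size()
        n_a, n_b = df["_fa"].nunique(), df["_fb"].nunique()
        if n_a < 2 or n_b < 2 or len(cells) != n_a * n_b or (cells < 2).any():
            raise ValueError(
                "two-way ANOVA needs >= 2 levels per factor and every "
                "factorial cell populated with n >= 2"
            )
        model = smf.ols("value ~ C(_fa) * C(_fb)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        inter = anova.loc["C(_fa):C(_fb)"]
        cell_label = (df["_fa"].astype(str) + ":" + df["_fb"].astype(str)).to_numpy()
        pairwise = _tukey_table(df["value"].to_numpy(dtype=float), cell_label)
        cell_groups = {
            k: g["value"].to_numpy(dtype=float)
            for k, g in df.groupby(df["_fa"].astype(str) + ":" + df["_fb"].astype(str))
        }
        labels = list(cell_groups)
        stats_pairs = [_mean_sem(cell_groups[k]) for k in labels]
        return ComparisonResult(
            measure=measure,
            groups=labels,
            n_per_group=[cell_groups[k].size for k in labels],
            means=[m for m, _ in stats_pairs],
            sems=[s for _, s in stats_pairs],
            normality_test="shapiro",
            normality_p=[_normality(cell_groups[k])[1] for k in labels],
            test="two_way_anova+tukey",
            statistic=float(inter["F"]),
            p_value=float(inter["PR(>F)"]),
            pairwise=pairwise,
            extra={"anova_table": anova},
        )
    raise ValueError(f"unknown design {design!r}")


def figure_table(measures: pd.DataFrame) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Run the appropriate comparison for every measure in a cohort table.

    ``measures`` is long-form with columns ``subject_id, group_label,
    measure, value``.  Measures with two groups go through the
    normality-gated two-group path, three or more through one-way
    ANOVA + Tukey, and single-group measures are reported descriptively.
    Measures listed with no usable data are skipped (reported as absent in
    the returned table), never fatal.
    """
    for col in ("subject_id", "group_label", "measure", "value"):
        if col not in measures.columns:
            raise ValueError(f"measures table missing column {col!r}")
    results: list[ComparisonResult] = []
    rows: list[dict] = []
    for name, sub in measures.groupby("measure", sort=False):
        sub = sub.dropna(subset=["value"])
        by_group = {k: g["value"].to_numpy(dtype=float) for k, g in sub.groupby("group_label")}
        if not by_group:
            rows.append({"measure": name, "test": "absent", "p_value": np.nan})
            continue
        try:
            if len(by_group) == 1:
                ((label, vals),) = by_group.items()
                m, s = _mean_sem(vals)
                res = ComparisonResult(
                    measure=name, groups=[label], n_per_group=[vals.size],
                    means=[m], sems=[s], normality_test="", normality_p=[],
                    test="descriptive", statistic=float("nan"), p_value=float("nan"),
                )
            elif len(by_group) == 2:
                (la, xa), (lb, xb) = by_group.items()
                res = compare_two_groups(xa, xb, labels=(la, lb), measure=name)
            else:
                res = compare_many_groups(by_group, design="one_way", measure=name)
        except ValueError as exc:
            rows.append({"measure": name, "test": f"absent ({exc})", "p_value": np.nan})
            continue
        results.append(res)
        rows.append(res.to_row())
    return results, pd.DataFrame(rows)
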