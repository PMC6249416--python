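"""Group-comparison statistics and table-style reporting.

Covers the screening-then-test flow typical of phenotyping studies:
normality (Shapiro-Wilk) and equal-variance (Brown-Forsythe) checks,
two-sample t / rank-sum / one- or two-way ANOVA with Bonferroni or
Holm-Sidak adjusted post-hoc contrasts, plus recomputation of a t
statistic from printed mean +/- SEM summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "t_from_summary", "compare_groups", "table_report"]


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean +/- SEM with group size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if self.n < 2:
            raise ValueError("group size must be >= 2")


def t_from_summary(a: GroupSummary, b: GroupSummary) -> dict:
    """Student's t recomputed from mean +/- SEM summaries.

    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2), the SE combination
    implied by per-group SEMs, with the pooled df = n_a + n_b - 2 that
    printed t(df) values use.  A Welch-Satterthwaite df is available via
    ``welch_df`` in the result for unequal-variance reporting.
    """
    se = np.hypot(a.sem, b.sem)
    if se == 0:
        raise ValueError("both SEMs are zero; t undefined")
    t = (a.mean - b.mean) / se
    df = a.n + b.n - 2
    va, vb = a.sem ** 2, b.sem ** 2
    welch_df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": int(df), "p": float(p), "welch_df": float(welch_df)}


def _screen(groups) -> dict:
    """Normality and equal-variance screening."""
    normal = True
    for g in groups:
        if len(g) >= 3:
            if sps.shapiro(g).pvalue < 0.05:
                normal = False
    # Brown-Forsythe: Levene's test with median centring
    equal_var = True
    if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
        equal_var = sps.levene(*groups, center="median").pvalue >= 0.05
    return {"normal": normal, "equal_variance": equal_var}


def compare_groups(
    data: pd.DataFrame,
    value: str,
    between: str,
    between2: str | None = None,
    adjust: str = "holm-sidak",
    alpha: float = 0.05,
) -> dict:
    """Screen-then-test group comparison on raw per-animal data.

    ``data`` is long-format with a value column and one or two factor
    columns.  Two groups: Student's t (rank-sum when screening fails);
    one factor with >= 3 levels: one-way ANOVA; two factors: two-way
    ANOVA with interaction (statsmodels OLS).  Post-hoc pairwise
    contrasts are adjusted with Holm-Sidak (default) or Bonferroni.
    All decisions and adjusted p-values are returned in the report.
    """
    if adjust not in ("holm-sidak", "bonferroni"):
        raise ValueError("adjust must be 'holm-sidak' or 'bonferroni'")
    report: dict = {"value": value, "alpha": alpha, "adjust": adjust}
    if between2 is None:
        levels = sorted(data[between].dropna().unique())
        groups = [data.loc[data[between] == lv, value].dropna().to_numpy() for lv in levels]
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty group cell")
        report["screening"] = _screen(groups)
        parametric = report["screening"]["normal"] and report["screening"]["equal_variance"]
        if len(levels) == 2:
            if parametric:
                res = sps.ttest_ind(groups[0], groups[1])
                report["test"] = "student-t"
                report["statistic"], report["p"] = float(res.statistic), float(res.pvalue)
                report["df"] = len(groups[0]) + len(groups[1]) - 2
            else:
                res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
                report["test"] = "rank-sum"
                report["statistic"], report["p"] = float(res.statistic), float(res.pvalue)
        else:
            if parametric:
                res = sps.f_oneway(*groups)
                report["test"] = "one-way-anova"
            else:
                res = sps.kruskal(*groups)
                report["test"] = "kruskal-wallis"
            report["statistic"], report["p"] = float(res.statistic), float(res.pvalue)
            report["posthoc"] = _pairwise(groups, levels, parametric, adjust)
        return report

    # two-way ANOVA with interaction
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    counts = data.groupby([between, between2])[value].count()
    if (counts == 0).any():
        raise ValueError("unbalanced design with empty cells")
    d = data.rename(columns={value: "y", between: "f1", between2: "f2"})
    model = ols("y ~ C(f1) * C(f2)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    report["test"] = "two-way-anova"
    report["anova"] = {
        str(idx): {"F": float(row["F"]), "p": float(row["PR(>F)"])}
        for idx, row in table.iterrows()
        if str(idx) != "Residual"
    }
    # post-hoc: factor-1 contrasts within each level of factor 2
    cells = []
    for lv2 in sorted(d["f2"].unique()):
        sub = d[d["f2"] == lv2]
        lv1s = sorted(sub["f1"].unique())
        gs = [sub.loc[sub["f1"] == lv, "y"].to_numpy() for lv in lv1s]
        cells.append((lv2, lv1s, gs))
    raw_p, labels = [], []
    for lv2, lv1s, gs in cells:
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                raw_p.append(float(sps.ttest_ind(gs[i], gs[j]).pvalue))
                labels.append(f"{lv1s[i]} vs {lv1s[j]} @ {lv2}")
    report["posthoc"] = _adjusted(labels, raw_p, adjust)
    return report


def _pairwise(groups, levels, parametric, adjust):
    raw_p, labels = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if parametric:
                p = float(sps.ttest_ind(groups[i], groups[j]).pvalue)
            else:
                p = float(
                    sps.mannwhitneyu(groups[i], groups[j], alternative="two-sided").pvalue
                )
            raw_p.append(p)
            labels.append(f"{levels[i]} vs {levels[j]}")
    return _adjusted(labels, raw_p, adjust)


def _adjusted(labels, raw_p, adjust):
    from statsmodels.stats.multitest import multipletests

    method = "holm-sidak" if adjust == "holm-sidak" else "bonferroni"
    if not raw_p:
        return []
    _, adj, _, _ = multipletests(raw_p, method=method)
    return [
        {"contrast": lab, "p_raw": pr, "p_adj": float(pa)}
        for lab, pr, pa in zip(labels, raw_p, adj)
    ]


def table_report(metrics: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Table-style summary: mean +/- SEM per group per metric plus a
    two-group test where applicable.

    ``metrics`` is one row per animal, one column per metric, plus a
    grouping column.  Output ordering is deterministic (sorted metric
    then group); a group of a single animal yields NaN SEM and is
    flagged in the ``note`` column.
    """
    rows = []
    levels = sorted(metrics[grouping].dropna().unique())
    metric_cols = sorted(c for c in metrics.columns if c != grouping)
    for col in metric_cols:
        stats_row: dict = {"metric": col}
        note = ""
        groups = []
        for lv in levels:
            vals = metrics.loc[metrics[grouping] == lv, col].dropna().to_numpy(float)
            groups.append(vals)
            stats_row[f"{lv}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
            stats_row[f"{lv}_sem"] = (
                float(sps.sem(vals)) if vals.size > 1 else float("nan")
            )
            stats_row[f"{lv}_n"] = int(vals.size)
            if vals.size < 2:
                note = "SEM undefined for n<2"
        if len(levels) == 2 and all(g.size >= 2 for g in groups):
            res = sps.ttest_ind(groups[0], groups[1])
            stats_row["t"] = float(res.statistic)
            stats_row["p"] = float(res.pvalue)
        stats_row["note"] = note
        rows.append(stats_row)
    return pd.DataFrame(rows).set_index("metric")
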