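"""Cohort statistics: normality, subgroup comparisons, log-age correlations.

Mirrors a standard clinical-cohort workflow: Anderson–Darling normality
per group decides between mean±SD and median/IQR descriptives and between
Welch's t-test and the Wilcoxon rank-sum for pairwise contrasts; subgroup
differences are screened with a one-way ANOVA omnibus at 5%, and
geometric variables are correlated with the natural logarithm of age.
Groups below a minimum size are excluded from testing (but described).
No multiple-testing correction is applied; reports flag this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("sex", "diagnosis", "rvot_type", "dysfunction")


@dataclass
class NormalityResult:
    statistic: float
    critical_5pct: float
    normal: bool


@dataclass
class ComparisonResult:
    category: str
    variable: str
    omnibus_p: float
    pairwise: list = field(default_factory=list)  # (group_a, group_b, test, p)
    descriptives: dict = field(default_factory=dict)
    excluded_groups: list = field(default_factory=list)


def normality(values, alpha: float = 0.05) -> NormalityResult:
    """Anderson–Darling test against the normal family at the 5% level."""
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(values) == 0:
        warnings.warn("constant input; flagged non-normal")
        return NormalityResult(np.inf, np.nan, False)
    with warnings.catch_warnings():
        # the critical-value API is what the 5% decision rule needs
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(values, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float)
    idx = int(np.argmin(np.abs(levels - 100 * alpha)))
    crit = float(res.critical_values[idx])
    return NormalityResult(float(res.statistic), crit, bool(res.statistic < crit))


def _describe(values, normal: bool) -> dict:
    values = np.asarray(values, dtype=float)
    if normal:
        return dict(
            n=len(values),
            normal=True,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)),
        )
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return dict(n=len(values), normal=False, median=float(med), iqr=float(q3 - q1))


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    category: str,
    alpha: float = 0.05,
    min_group: int = 4,
) -> ComparisonResult:
    """Omnibus ANOVA across subgroups; pairwise tests when significant.

    Pairwise contrasts use Welch's t-test when both groups pass the
    normality check, the Wilcoxon rank-sum otherwise.  Groups smaller than
    ``min_group`` are excluded from testing and listed separately.
    """
    groups = {
        str(g): sub[variable].to_numpy(dtype=float)
        for g, sub in table.groupby(category, sort=False)
    }
    eligible = {g: v for g, v in groups.items() if len(v) >= min_group}
    excluded = [g for g in groups if g not in eligible]
    desc = {}
    for g, v in groups.items():
        try:
            flag = normality(v).normal if len(v) >= 8 else len(v) >= 2 and _is_normalish(v)
        except ValueError:
            flag = False
        desc[g] = _describe(v, flag)
    if len(eligible) < 2:
        return ComparisonResult(category, variable, np.nan, [], desc, excluded)
    fstat, omnibus_p = stats.f_oneway(*eligible.values())
    pairwise = []
    if omnibus_p < alpha:
        names = list(eligible)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = eligible[names[i]], eligible[names[j]]
                both_normal = desc[names[i]].get("normal") and desc[names[j]].get("normal")
                if both_normal:
                    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                    test = "welch-t"
                else:
                    p = float(stats.ranksums(a, b).pvalue)
                    test = "wilcoxon"
                pairwise.append((names[i], names[j], test, p))
    return ComparisonResult(
        category, variable, float(omnibus_p), pairwise, desc, excluded
    )


def _is_normalish(v) -> bool:
    # too small for Anderson-Darling: fall back to Shapiro at the same level
    if len(v) < 3 or np.ptp(v) == 0:
        return False
    return bool(stats.shapiro(v).pvalue > 0.05)


def correlate_with_log_age(table: pd.DataFrame, variable: str):
    """Pearson correlation of a variable with ln(age)."""
    age = table["age_years"].to_numpy(dtype=float)
    if np.any(age <= 0):
        raise ValueError("ages must be positive")
    y = table[variable].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(y) == 0 or np.ptp(age) == 0:
        warnings.warn("zero variance; correlation undefined")
        return np.nan, np.nan
    r, p = stats.pearsonr(y, np.log(age))
    return float(r), float(p)


def correlate_scores_with_geometry(
    scores: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and p) between each mode's shape vectors and SA/L_RVOT/D_AVE.

    Both frames must carry ``subject_id``; rows are aligned on it.
    """
    merged = scores.merge(summaries, on="subject_id", validate="one_to_one")
    mode_cols = [c for c in scores.columns if c.startswith("mode")]
    rows = []
    for mc in mode_cols:
        for var in ("sa", "l_rvot", "d_ave"):
            r, p = stats.pearsonr(merged[mc], merged[var])
            rows.append(dict(mode=mc, variable=var, r=float(r), p=float(p)))
    return pd.DataFrame(rows)


def comparisons_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tidy table: one row per omnibus / pairwise test."""
    rows = []
    for res in results:
        rows.append(
            dict(
                category=res.category,
                variable=res.variable,
                test="anova",
                group_a="all",
                group_b="",
                p=res.omnibus_p,
            )
        )
        for a, b, test, p in res.pairwise:
            rows.append(
                dict(
                    category=res.category,
                    variable=res.variable,
                    test=test,
                    group_a=a,
                    group_b=b,
                    p=p,
                )
            )
    return pd.DataFrame(rows)


def descriptives_report(results: list[ComparisonResult]) -> str:
    """Plain-text per-subgroup summary statistics (boxplot-style report)."""
    lines = ["Subgroup descriptives (no multiple-testing correction applied)"]
    for res in results:
        lines.append(f"\n{res.variable} by {res.category} "
                     f"(omnibus ANOVA p={res.omnibus_p:.3g})")
        for g, d in res.descriptives.items():
            if d.get("normal"):
                lines.append(
                    f"  {g:12s} n={d['n']:3d}  mean={d['mean']:.2f} ± {d['sd']:.2f}"
                )
            else:
                lines.append(
                    f"  {g:12s} n={d['n']:3d}  median={d.get('median', np.nan):.2f} "
                    f"(IQR {d.get('iqr', np.nan):.2f})"
                )
        if res.excluded_groups:
            lines.append(f"  excluded from testing (n too small): "
                         f"{', '.join(res.excluded_groups)}")
        for a, b, test, p in res.pairwise:
            lines.append(f"  {a} vs {b}: {test} p={p:.3g}")
    return "\n".join(lines)
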