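"""Group-level statistics: correlations, per-K Welch tests, mixed ANOVA.

The two-way mixed ANOVA (one within-subject factor, one between-subject
factor) is implemented from first principles with the classical univariate
sums of squares, since it carries the headline behavioral contrast; Pearson
correlations and Welch t-tests delegate to scipy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "pearson_correlation",
    "ttest_two_sample",
    "mixed_anova_2way",
    "per_k_group_comparison",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    pvalue: float
    df2: float | None = None
    estimate: float | None = None  # r, or mean difference / effect direction
    direction: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.pvalue) and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def pearson_correlation(x, y) -> TestResult:
    """Sample Pearson r with the two-sided t-transform p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return TestResult(name="pearson", statistic=r, df=len(x) - 2,
                      pvalue=float(res.pvalue), estimate=r,
                      direction=int(np.sign(r)))


def ttest_two_sample(a, b) -> TestResult:
    """Welch (unequal-variance) two-sample two-tailed t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = sps.ttest_ind(a, b, equal_var=False)
    diff = float(a.mean() - b.mean())
    return TestResult(name="welch_t", statistic=float(res.statistic),
                      df=float(res.df), pvalue=float(res.pvalue),
                      estimate=diff, direction=int(np.sign(diff)))


def _anova_from_arrays(groups: list[np.ndarray]) -> dict[str, TestResult]:
    """Mixed ANOVA core: one (n_g x a) matrix per between-group."""
    a_lev = groups[0].shape[1]
    n_g = np.array([g.shape[0] for g in groups], float)
    n_tot = n_g.sum()
    b_lev = len(groups)
    allv = np.concatenate(groups, axis=0)
    grand = allv.mean()

    subj_means = allv.mean(axis=1)
    group_means = np.array([g.mean() for g in groups])
    within_means = allv.mean(axis=0)  # per within-level, over all subjects
    cell_means = np.stack([g.mean(axis=0) for g in groups])  # (b, a)

    ss_between_subj = a_lev * ((subj_means - grand) ** 2).sum()
    ss_group = a_lev * (n_g * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_cond = n_tot * ((within_means - grand) ** 2).sum()
    ss_cells = (n_g[:, None] * (cell_means - grand) ** 2).sum()
    ss_int = ss_cells - ss_group - ss_cond
    ss_total = ((allv - grand) ** 2).sum()
    ss_err = ss_total - ss_cells - ss_subj_within

    df_group = b_lev - 1
    df_subj = n_tot - b_lev
    df_cond = a_lev - 1
    df_int = df_group * df_cond
    df_err = df_cond * df_subj

    def f_result(name: str, ss: float, df1: float, ss_e: float, df_e: float) -> TestResult:
        ms, ms_e = ss / df1, ss_e / df_e
        f = ms / ms_e if ms_e > 0 else np.inf
        p = float(sps.f.sf(f, df1, df_e)) if np.isfinite(f) else 0.0
        return TestResult(name=name, statistic=float(f), df=df1, df2=df_e, pvalue=p)

    return {
        "between": f_result("group", ss_group, df_group, ss_subj_within, df_subj),
        "within": f_result("condition", ss_cond, df_cond, ss_err, df_err),
        "interaction": f_result("interaction", ss_int, df_int, ss_err, df_err),
    }


def mixed_anova_2way(table: pd.DataFrame, dv: str, within: str, between: str,
                     subject: str) -> dict[str, TestResult]:
    """Two-way mixed-design ANOVA on a long-format table.

    ``within`` is the repeated factor (every subject must contribute exactly
    one observation per level); ``between`` the grouping factor.  Returns F
    tests for the between main effect (against subjects-within-groups), the
    within main effect and the interaction (against the within-subject
    residual).
    """
    levels = sorted(table[within].unique().tolist())
    grp_labels = sorted(table[between].unique().tolist())
    if len(levels) < 2 or len(grp_labels) < 2:
        raise ValueError("both factors need at least two levels")
    groups = []
    for g in grp_labels:
        sub = table[table[between] == g]
        wide = sub.pivot_table(index=subject, columns=within, values=dv,
                               aggfunc="first")
        if wide.isna().any().any() or list(wide.columns) != levels:
            raise ValueError(
                f"missing cell: group {g!r} lacks a complete {within} design")
        counts = sub.groupby(subject)[within].count()
        if (counts != len(levels)).any():
            raise ValueError("each subject must contribute one row per level")
        groups.append(wide.to_numpy(float))
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    return _anova_from_arrays(groups)


def per_k_group_comparison(metrics: pd.DataFrame, group_col: str = "group",
                           k_col: str = "K",
                           value_cols: tuple[str, ...] = ("C", "L", "gamma", "lambda"),
                           alpha: float = 0.05,
                           fdr: bool = False) -> pd.DataFrame:
    """Welch t-test between the two groups at every degree K for each metric.

    Mirrors the per-K significance marks of the study's network figures; no
    multiple-testing correction by default (``fdr=True`` switches on
    Benjamini-Hochberg across K within each metric).
    """
    labels = sorted(metrics[group_col].unique().tolist())
    if len(labels) != 2:
        raise ValueError("per-K comparison expects exactly two groups")
    g1, g2 = labels
    rows = []
    for metric in value_cols:
        for k in sorted(metrics[k_col].unique().tolist()):
            sel = metrics[metrics[k_col] == k]
            a = sel.loc[sel[group_col] == g1, metric].to_numpy(float)
            b = sel.loc[sel[group_col] == g2, metric].to_numpy(float)
            res = ttest_two_sample(a, b)
            rows.append({
                "metric": metric, "K": k, "t": res.statistic, "df": res.df,
                "p": res.pvalue, "mean_diff": res.estimate,
                "direction": res.direction,
            })
    out = pd.DataFrame(rows)
    if fdr:
        out["p_adj"] = np.concatenate([
            benjamini_hochberg(out.loc[out.metric == m, "p"].to_numpy())
            for m in value_cols
        ])
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(n)
    out[order] = adj
    return out
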