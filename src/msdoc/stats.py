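"""Group-comparison statistics for cohort and microstate parameters.

Continuous variables are compared with a pooled-variance Student t (or
Mann-Whitney U with a tie-corrected normal approximation when routed as
non-normal), categorical variables with a Pearson chi-square, paired
pre/post microstate parameters with a two-level repeated-measures ANOVA
(whose F equals the squared paired t), and families of p-values are
adjusted with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    p_adjusted: float | None = None
    note: str = ""


def two_sample_t_pooled(x, y) -> StatResult:
    """Student t with pooled variance; statistic sign follows mean(x) - mean(y)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    df = len(x) + len(y) - 2
    sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return StatResult("pooled t", 0.0, df, 1.0, note="zero pooled variance")
        return StatResult(
            "pooled t", np.inf * np.sign(x.mean() - y.mean()), df, 0.0,
            note="zero pooled variance, unequal means",
        )
    res = sps.ttest_ind(x, y, equal_var=True)
    return StatResult("pooled t", float(res.statistic), df, float(res.pvalue))


def paired_t(before, after) -> StatResult:
    """One-sample t on the paired differences (before - after)."""
    before, after = np.asarray(before, float), np.asarray(after, float)
    if len(before) != len(after) or len(before) < 2:
        raise ValueError("need equal-length paired samples, n >= 2")
    d = before - after
    df = len(d) - 1
    if d.std(ddof=1) == 0:
        stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        return StatResult("paired t", stat, df, 1.0 if stat == 0 else 0.0,
                          note="zero-variance differences")
    res = sps.ttest_rel(before, after)
    return StatResult("paired t", float(res.statistic), df, float(res.pvalue))


def mann_whitney(x, y) -> StatResult:
    """Mann-Whitney U with tie-corrected normal approximation (two-sided z)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return StatResult("Mann-Whitney U", u, None, 1.0, note="all values tied")
    z = (u - mu) / np.sqrt(sigma2)
    p = 2 * sps.norm.sf(abs(z))
    return StatResult("Mann-Whitney U", u, None, float(p), note=f"z={z:.3f}")


def chi_square(table, correction: bool = False) -> StatResult:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=correction)
    return StatResult("chi-square", float(chi2), int(df), float(p))


def rm_anova_two_level(pre, post) -> StatResult:
    """One-way repeated-measures ANOVA with two time levels.

    Computed from the sums of squares directly; algebraically F equals the
    squared paired t with df (1, n-1).
    """
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    if len(pre) != len(post) or len(pre) < 2:
        raise ValueError("need paired samples, n >= 2")
    n = len(pre)
    data = np.stack([pre, post], axis=1)
    grand = data.mean()
    subj_means = data.mean(axis=1)
    time_means = data.mean(axis=0)
    ss_time = n * np.sum((time_means - grand) ** 2)
    ss_subj = 2 * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_time - ss_subj
    df_time, df_err = 1, n - 1
    ms_err = ss_err / df_err
    scale = max(ss_total, np.finfo(float).tiny)
    if ms_err <= 1e-12 * scale:
        if ss_time <= 1e-12 * scale:
            return StatResult("RM-ANOVA", 0.0, (df_time, df_err), 1.0,
                              note="zero within-subject variance")
        return StatResult("RM-ANOVA", np.inf, (df_time, df_err), 0.0,
                          note="zero within-subject variance")
    f = (ss_time / df_time) / ms_err
    p = float(sps.f.sf(f, df_time, df_err))
    return StatResult("RM-ANOVA", float(f), (df_time, df_err), p)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return adj
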