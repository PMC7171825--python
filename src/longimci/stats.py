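"""Demographic group comparisons from printed summary statistics.

Cohort tables in the MCI literature report per-group mean ± SD for
continuous covariates and male/female counts for gender.  These helpers
reproduce the standard comparisons directly from such summaries: a
pooled-variance two-sample t-test (df = n1 + n2 − 2, two-sided p) and a
Pearson chi-square on a 2x2 table without continuity correction (a
Yates-corrected variant is available by flag).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .types import GroupSummary, TwoByTwo

__all__ = [
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "demographic_table",
]


def two_sample_t_from_summary(
    g1: GroupSummary, g2: GroupSummary
) -> tuple[float, int, float]:
    """Pooled two-sample t-test from (mean, sd, n) summaries.

    Returns ``(t, df, p)`` with t signed as group1 − group2.  A zero
    pooled variance with equal means gives t = 0, p = 1; with unequal
    means the statistic is undefined and an error is raised.
    """
    df = g1.n + g2.n - 2
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    return float(t), df, float(p)


def chi_square_2x2(
    table: TwoByTwo, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test on a 2x2 contingency table.

    Returns ``(chi2, df, p)`` with df = 1.  No continuity correction by
    default; ``correction=True`` applies the Yates adjustment.

    Raises
    ------
    ValueError
        If any row or column margin is zero (expected counts undefined).
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all margins of the 2x2 table must be positive")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), 1, float(res.pvalue)


def demographic_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Baseline group-comparison table for a two-group MCI subject table.

    Rows: gender (chi-square on the male/female 2x2), baseline age,
    MMSE and ADAS-cog (pooled t-tests from the raw values).  Expects
    ``group`` in {sMCI, pMCI} plus ``age``, ``gender``, ``mmse_bl``,
    ``adas_bl`` columns.
    """
    s = subjects[subjects["group"] == "sMCI"]
    p = subjects[subjects["group"] == "pMCI"]
    if len(s) < 2 or len(p) < 2:
        raise ValueError("need at least 2 subjects per MCI group")

    rows = []
    tab = TwoByTwo(
        int((s["gender"] == 1).sum()), int((s["gender"] == 0).sum()),
        int((p["gender"] == 1).sum()), int((p["gender"] == 0).sum()),
    )
    chi2, _, pval = chi_square_2x2(tab)
    rows.append({"variable": "gender", "statistic": chi2, "test": "chi-square",
                 "p_value": pval})
    for var, col in (("age", "age"), ("mmse_bl", "mmse_bl"), ("adas_bl", "adas_bl")):
        gs = GroupSummary(float(s[col].mean()), float(s[col].std(ddof=1)), len(s))
        gp = GroupSummary(float(p[col].mean()), float(p[col].std(ddof=1)), len(p))
        t, _, pval = two_sample_t_from_summary(gs, gp)
        rows.append({"variable": var, "statistic": t, "test": "two-sample t",
                     "p_value": pval})
    return pd.DataFrame(rows)
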