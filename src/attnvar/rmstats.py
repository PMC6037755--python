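"""Session-level repeated-measures inference.

Sessions — never units or pairs — are the units of analysis: measurements
are first averaged within a session, and statistics are computed across
sessions.  One-way repeated-measures ANOVA (session as the random factor,
attention condition fixed) is implemented directly; the two-factor
within-subject design (e.g. condition x microsaccade direction) delegates
to statsmodels' AnovaRM.  Post-hoc pairwise comparisons use the
Tukey-Kramer studentized-range method on the condition means with the
ANOVA's error mean square.  No sphericity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["RmAnovaResult", "rm_anova", "rm_anova_two_way", "ab_contrast_test", "bonferroni_alpha"]


@dataclass
class RmAnovaResult:
    f_stat: float
    df_effect: int
    df_error: int
    p_value: float
    condition_means: np.ndarray
    condition_sem: np.ndarray
    ms_error: float
    posthoc_p: dict = field(default_factory=dict)


def rm_anova(values: np.ndarray, posthoc: bool = True) -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a (sessions x conditions) matrix.

    Sessions with any missing (NaN) cell are dropped (listwise).  With two
    conditions, F equals the squared paired-t statistic.  Tukey-Kramer
    post-hoc p-values are computed from the studentized range with the
    within-subject error term.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be sessions x conditions")
    v = v[~np.isnan(v).any(axis=1)]
    n, k = v.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 sessions and >= 2 conditions")
    grand = v.mean()
    ss_cond = n * ((v.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((v.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((v - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_c, df_e = k - 1, (k - 1) * (n - 1)
    ms_c = ss_cond / df_c
    ms_e = ss_err / df_e if df_e > 0 else np.nan
    tiny = 1e-12 * (ss_tot + 1.0)
    if ms_e <= tiny:
        f = 0.0 if ms_c <= tiny else np.inf
        p = 1.0 if ms_c <= tiny else 0.0
    else:
        f = ms_c / ms_e
        p = float(stats.f.sf(f, df_c, df_e))
    res = RmAnovaResult(
        f_stat=float(f), df_effect=df_c, df_error=df_e, p_value=p,
        condition_means=v.mean(axis=0), condition_sem=v.std(axis=0, ddof=1) / np.sqrt(n),
        ms_error=float(ms_e),
    )
    if posthoc and np.isfinite(ms_e) and ms_e > 0:
        means = v.mean(axis=0)
        for i in range(k):
            for j in range(i + 1, k):
                q = abs(means[i] - means[j]) / np.sqrt(ms_e / n)
                res.posthoc_p[(i, j)] = float(stats.studentized_range.sf(q, k, df_e))
    return res


def rm_anova_two_way(values: np.ndarray) -> dict:
    """Two-factor within-subject ANOVA on (sessions x levelsA x levelsB).

    Returns F, dfs and p for factor A, factor B and the interaction
    (statsmodels AnovaRM).  Reported in the "F(a, b, subjects)" style:
    df for each fixed factor with the session random factor.
    """
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    v = np.asarray(values, dtype=float)
    n, a, b = v.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append(dict(subject=s, A=i, B=j, y=v[s, i, j]))
    df = pd.DataFrame(rows)
    tab = AnovaRM(df, depvar="y", subject="subject", within=["A", "B"]).fit().anova_table
    out = {}
    for name, key in (("A", "A"), ("B", "B"), ("A:B", "A:B")):
        row = tab.loc[key]
        out[name] = dict(F=float(row["F Value"]), df1=int(row["Num DF"]),
                         df2=int(row["Den DF"]), p=float(row["Pr > F"]))
    return out


def ab_contrast_test(values_ai: np.ndarray, values_ab: np.ndarray, values_ao: np.ndarray):
    """One-tailed t-test for AB elevation.

    Per-session contrast c = AB - (AI + AO)/2; one-sample t against 0 with
    the one-tailed alternative that AB is greater (the direction predicted a
    priori by the attentional-fluctuation model).  Returns (t, df, p).
    """
    ai = np.asarray(values_ai, dtype=float)
    ab = np.asarray(values_ab, dtype=float)
    ao = np.asarray(values_ao, dtype=float)
    ok = np.isfinite(ai) & np.isfinite(ab) & np.isfinite(ao)
    c = ab[ok] - 0.5 * (ai[ok] + ao[ok])
    n = len(c)
    if n < 2:
        raise ValueError("need >= 2 sessions with all three conditions")
    sd = c.std(ddof=1)
    if sd == 0:
        if np.allclose(c, 0):
            return 0.0, n - 1, 0.5
        raise ValueError("zero-variance contrast with nonzero mean; degenerate")
    t = c.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, n - 1))
    return float(t), n - 1, p


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Corrected per-comparison alpha = alpha/m for m comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
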