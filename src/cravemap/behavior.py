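"""Behavioral analyses: one-way repeated-measures ANOVA with Mauchly's
sphericity test and Huynh-Feldt correction, Bonferroni-corrected paired
post hocs, and the baseline stimulus-assignment check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONDITIONS


class BehaviorError(ValueError):
    pass


def summarize_ratings(ratings: pd.DataFrame,
                      conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Subject x condition mean rating table (missing trials dropped)."""
    table = ratings.dropna(subset=["rating"])
    summary = table.pivot_table(index="subject", columns="condition",
                                values="rating", aggfunc="mean")
    missing = [c for c in conditions if c not in summary.columns]
    if missing:
        raise BehaviorError(f"conditions absent from ratings: {missing}")
    summary = summary[list(conditions)]
    if summary.isna().any().any():
        raise BehaviorError("missing subject x condition cells")
    return summary


def _as_matrix(summary) -> np.ndarray:
    x = summary.to_numpy(dtype=float) if isinstance(summary, pd.DataFrame) \
        else np.asarray(summary, dtype=float)
    if x.ndim != 2:
        raise BehaviorError("summary must be a 2D subject x condition table")
    if np.isnan(x).any():
        raise BehaviorError("missing cells in summary")
    if x.shape[0] < 3:
        raise BehaviorError("need at least 3 subjects")
    return x


@dataclass
class RmAnovaResult:
    f: float
    df1: float
    df2: float
    p: float
    epsilon_hf: float
    mauchly_w: float
    mauchly_p: float
    corrected: bool                 # Huynh-Feldt df correction applied
    f_uncorrected_df: tuple[float, float]
    p_uncorrected: float


def _mauchly(x: np.ndarray) -> tuple[float, float]:
    """Mauchly's W and its chi-square p value for a subject x k matrix."""
    n, k = x.shape
    # orthonormal contrast (Helmert) spanning the k-1 within differences
    m = np.zeros((k - 1, k))
    for i in range(k - 1):
        m[i, :i + 1] = 1.0
        m[i, i + 1] = -(i + 1.0)
        m[i] /= np.linalg.norm(m[i])
    s = np.cov(x, rowvar=False, ddof=1)
    t = m @ s @ m.T
    eig = np.linalg.eigvalsh(t)
    eig = np.clip(eig, 1e-300, None)
    d = k - 1
    w = float(np.prod(eig) / (np.mean(eig) ** d))
    chi_df = d * (d + 1) / 2 - 1
    f_corr = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(max(w, 1e-300))
    p = float(stats.chi2.sf(chi2, chi_df))
    return w, p


def _epsilons(x: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilons (HF clipped to <= 1)."""
    n, k = x.shape
    s = np.cov(x, rowvar=False, ddof=1)
    # double-centred covariance
    row = s.mean(axis=0, keepdims=True)
    dc = s - row - row.T + s.mean()
    d = k - 1
    denom = d * np.sum(dc * dc)
    if denom <= 0:          # degenerate (zero within-subject variance)
        return 1.0, 1.0
    gg = float(np.trace(dc) ** 2 / denom)
    hf = (n * d * gg - 2.0) / (d * (n - 1 - d * gg))
    hf = float(np.clip(hf, gg, 1.0))
    gg = float(np.clip(gg, 1.0 / d, 1.0))
    return gg, hf


def rm_anova(summary, mauchly_alpha: float = 0.05) -> RmAnovaResult:
    """One-way within-subject ANOVA with Huynh-Feldt sphericity handling.

    With two conditions the test reduces to the paired t (F = t^2) and
    sphericity holds trivially (epsilon = 1).
    """
    x = _as_matrix(summary)
    n, k = x.shape
    if k < 2:
        raise BehaviorError("need at least 2 conditions")
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_cond = n * np.sum((col_means - grand) ** 2)
    resid = x - col_means[None, :] - row_means[:, None] + grand
    ss_err = np.sum(resid ** 2)
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = float(ms_cond / ms_err) if ms_err > 0 else 0.0
    p_unc = float(stats.f.sf(f, df1, df2)) if ms_err > 0 else 1.0

    if k == 2:
        return RmAnovaResult(f=f, df1=df1, df2=df2, p=p_unc, epsilon_hf=1.0,
                             mauchly_w=1.0, mauchly_p=1.0, corrected=False,
                             f_uncorrected_df=(df1, df2), p_uncorrected=p_unc)

    w, p_mauchly = _mauchly(x)
    _gg, hf = _epsilons(x)
    corrected = p_mauchly < mauchly_alpha
    if corrected:
        cdf1, cdf2 = df1 * hf, df2 * hf
        p = float(stats.f.sf(f, cdf1, cdf2)) if ms_err > 0 else 1.0
    else:
        cdf1, cdf2, p = df1, df2, p_unc
    return RmAnovaResult(f=f, df1=cdf1, df2=cdf2, p=p, epsilon_hf=hf,
                         mauchly_w=w, mauchly_p=p_mauchly, corrected=corrected,
                         f_uncorrected_df=(df1, df2), p_uncorrected=p_unc)


def paired_posthocs(summary, comparisons: list[tuple[str, str]],
                    family_alpha: float = 0.05) -> pd.DataFrame:
    """Dependent t tests with the Bonferroni per-comparison threshold.

    Reports raw p next to the adjusted threshold ``family_alpha / m`` (0.017
    for three comparisons at 0.05) and a Bonferroni-adjusted p for
    convenience.
    """
    if not isinstance(summary, pd.DataFrame):
        raise BehaviorError("paired_posthocs needs a labelled DataFrame summary")
    m = len(comparisons)
    if m < 1:
        raise BehaviorError("no comparisons given")
    threshold = family_alpha / m
    rows = []
    for a, b in comparisons:
        for name in (a, b):
            if name not in summary.columns:
                raise BehaviorError(f"unknown condition {name!r}")
        res = stats.ttest_rel(summary[a], summary[b])
        rows.append({"comparison": f"{a} vs {b}", "t": float(res.statistic),
                     "df": len(summary) - 1, "p": float(res.pvalue),
                     "p_bonferroni": float(min(res.pvalue * m, 1.0)),
                     "threshold": threshold,
                     "significant": bool(res.pvalue < threshold)})
    return pd.DataFrame(rows)


def baseline_check(pre_ratings: pd.DataFrame) -> RmAnovaResult:
    """Assignment check: RM-ANOVA on per-subject per-strategy mean baseline
    ratings (uncorrected df: 2 and 2(n - 1))."""
    summary = summarize_ratings(pre_ratings)
    x = _as_matrix(summary)
    res = rm_anova(summary)
    # report the uncorrected test: the check is descriptive
    df1, df2 = res.f_uncorrected_df
    assert df2 == 2 * (x.shape[0] - 1)
    return RmAnovaResult(f=res.f, df1=df1, df2=df2, p=res.p_uncorrected,
                         epsilon_hf=res.epsilon_hf, mauchly_w=res.mauchly_w,
                         mauchly_p=res.mauchly_p, corrected=False,
                         f_uncorrected_df=(df1, df2),
                         p_uncorrected=res.p_uncorrected)
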