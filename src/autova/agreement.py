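"""Method-agreement statistics for paired manual vs automated acuities.

Implements the clinical validation toolkit: Bland-Altman bias with 95%
limits of agreement (mean difference +/- 1.96 SD), the two-way
random-effects absolute-agreement single-measure intraclass correlation
ICC(2,1) with its F-based confidence interval, Wilcoxon signed-rank and
Spearman correlation for the non-normal case, Shapiro-Wilk normality
screening, and the participant-level outlier filter (a participant is
excluded when |manual - automated| >= 0.4 logMAR in either eye).

Eyes are treated as independent measurement units, so n counts eyes, not
participants; the outlier filter alone works at the participant level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    degenerate: bool = False


def bland_altman(pairs: pd.DataFrame, method_a_col: str, method_b_col: str) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for differences a - b.

    Sample SD uses the n-1 denominator; the LoA multiplier is the fixed
    Normal quantile 1.96, the convention of the original method.
    """
    d = (pairs[method_a_col] - pairs[method_b_col]).dropna().to_numpy(dtype=float)
    if d.size < 2:
        raise AgreementError("Bland-Altman needs at least 2 paired values")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=int(d.size),
    )


def _two_way_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Mean squares of the two-way (subjects x methods) ANOVA without
    replication: rows, columns, residual."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_agreement(
    pairs: pd.DataFrame,
    method_a_col: str = "manual_logmar",
    method_b_col: str = "automated_logmar",
    model: str = "ICC(2,1)",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measure ICC between two measurement methods.

    ``ICC(2,1)`` (default) is the two-way random-effects absolute-agreement
    form: method-to-method offsets count against agreement, which is what
    an inter-method comparison needs. ``ICC(3,1)`` (consistency, fixed
    raters) is available for sensitivity analyses. Confidence limits follow
    the F-distribution construction of Shrout & Fleiss / McGraw & Wong.
    """
    sub = pairs[[method_a_col, method_b_col]].dropna()
    y = sub.to_numpy(dtype=float)
    n, k = y.shape
    if n < 5:
        raise AgreementError("ICC needs at least 5 subjects")
    if np.ptp(y) == 0:
        raise AgreementError("zero total variance: ICC undefined")
    msr, msc, mse = _two_way_mean_squares(y)

    if model == "ICC(3,1)":
        icc = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (f_l - 1) / (f_l + (k - 1))
        ci_high = (f_u - 1) / (f_u + (k - 1))
        return ICCResult(float(icc), float(ci_low), float(ci_high), model)
    if model != "ICC(2,1)":
        raise AgreementError(f"unknown ICC model {model!r}")

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # Satterthwaite df for the CI (McGraw & Wong, case A-1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mse) ** 2 / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f_star_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_star_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        ci_low = n * (msr - f_star_l * mse) / (
            f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        ci_high = n * (f_star_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_star_u * msr
        )
    else:
        ci_low = ci_high = 1.0
    return ICCResult(float(icc), float(ci_low), float(ci_high), "ICC(2,1)")


def wilcoxon_signed_rank(
    pairs: pd.DataFrame,
    method_a_col: str = "manual_logmar",
    method_b_col: str = "automated_logmar",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties in |d|, otherwise the normal approximation with
    tie-corrected variance. All differences zero is degenerate (p = 1).
    """
    d = (pairs[method_a_col] - pairs[method_b_col]).dropna().to_numpy(dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; Wilcoxon test degenerate")
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="degenerate", degenerate=True)
    has_ties = len(np.unique(np.abs(d))) < d.size
    if d.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), int(d.size), method)


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (vetted routine; valid for 3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if not 3 <= x.size <= 5000:
        raise AgreementError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise AgreementError("constant input: normality test undefined")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue), int(x.size), "shapiro-wilk")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise AgreementError("Spearman needs equal-length inputs with n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise AgreementError("constant input: Spearman rho undefined")
    res = sps.spearmanr(xa, ya)
    return TestResult(float(res.statistic), float(res.pvalue), int(xa.size), "spearman")


def outlier_filter(
    pairs: pd.DataFrame,
    threshold: float = 0.4,
    method_a_col: str = "manual_logmar",
    method_b_col: str = "automated_logmar",
    participant_col: str = "participant_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level outlier exclusion.

    A participant is flagged when |manual - automated| >= threshold in
    EITHER eye (boundary inclusive); both of that participant's eye-rows
    move to the flagged table. Differences sit on the 0.02 letter grid, so
    the comparison carries a 1e-9 tolerance to keep the boundary inclusive
    under float rounding.
    """
    if threshold <= 0:
        raise AgreementError("threshold must be positive")
    if pairs.empty:
        return pairs.copy(), pairs.copy()
    diff = (pairs[method_a_col] - pairs[method_b_col]).abs()
    eye_flag = diff >= (threshold - 1e-9)
    flagged_ids = set(pairs.loc[eye_flag.fillna(False), participant_col])
    is_flagged = pairs[participant_col].isin(flagged_ids)
    return pairs[~is_flagged].copy(), pairs[is_flagged].copy()


def agreement_report(
    pairs: pd.DataFrame,
    method_a_col: str = "manual_logmar",
    method_b_col: str = "automated_logmar",
    outlier_threshold: float = 0.4,
) -> dict:
    """One-stop summary used by the CLI: Bland-Altman, ICC, paired and
    correlation tests, normality of the differences, and the outlier split."""
    kept, flagged = outlier_filter(pairs, outlier_threshold, method_a_col, method_b_col)
    sub = pairs[[method_a_col, method_b_col]].dropna()
    ba = bland_altman(sub, method_a_col, method_b_col)
    icc = icc_agreement(sub, method_a_col, method_b_col)
    wil = wilcoxon_signed_rank(sub, method_a_col, method_b_col)
    d = (sub[method_a_col] - sub[method_b_col]).to_numpy(dtype=float)
    try:
        norm = shapiro_wilk(d)
        normality = {"statistic": norm.statistic, "p_value": norm.p_value}
    except AgreementError as exc:
        normality = {"error": str(exc)}
    try:
        rho = spearman_rho(sub[method_a_col], sub[method_b_col])
        corr = {"rho": rho.statistic, "p_value": rho.p_value}
    except AgreementError as exc:
        corr = {"error": str(exc)}
    return {
        "n_eyes": int(len(sub)),
        "bland_altman": {
            "mean_diff": ba.mean_diff,
            "sd_diff": ba.sd_diff,
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
        },
        "icc": {"value": icc.icc, "ci_low": icc.ci_low, "ci_high": icc.ci_high, "model": icc.model},
        "wilcoxon": {"statistic": wil.statistic, "p_value": wil.p_value, "method": wil.method},
        "normality": normality,
        "spearman": corr,
        "outliers": {
            "threshold": outlier_threshold,
            "n_flagged_participants": int(flagged["participant_id"].nunique()) if not flagged.empty else 0,
            "n_flagged_eyes": int(len(flagged)),
        },
    }
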