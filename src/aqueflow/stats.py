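"""Agreement and group statistics: ICC(2,1), Bland-Altman, Dice, ANOVA, OLS.

The intraclass correlation follows the Shrout-Fleiss two-way random-effects,
single-measurement, absolute-agreement model ICC(2,1), computed directly
from the two-way ANOVA mean squares.  Agreement labels follow the
conventional thresholds: < 0.3 lack, 0.31-0.50 weak, 0.51-0.70 moderate,
0.71-0.90 strong, 0.91-1.00 very strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "icc21",
    "icc_label",
    "icc_agreement",
    "bland_altman",
    "dice",
    "anova_oneway",
    "linreg",
]


@dataclass
class AgreementResult:
    icc: float
    label: str
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    slope: float
    intercept: float
    r2: float


def icc_label(icc: float) -> str:
    if icc <= 0.30:
        return "lack"
    if icc <= 0.50:
        return "weak"
    if icc <= 0.70:
        return "moderate"
    if icc <= 0.90:
        return "strong"
    return "very strong"


def icc21(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is (n_subjects, k_raters).  From the two-way ANOVA mean
    squares (rows MSR, columns MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing values are not supported")
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        raise ValueError("zero total variance")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    )


def icc_agreement(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Agreement between two paired measurement series.

    Combines ICC(2,1) with its qualitative label, Bland-Altman bias and
    limits of agreement, and an OLS regression of b on a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    icc = icc21(np.column_stack([a, b]))
    bias, sd, lo, hi = bland_altman(a, b)
    res = sps.linregress(a, b)
    return AgreementResult(
        icc, icc_label(icc), bias, sd, lo, hi,
        float(res.slope), float(res.intercept), float(res.rvalue**2),
    )


def bland_altman(a, b) -> tuple[float, float, float, float]:
    """Bland-Altman bias, SD of differences, and 95% limits of agreement."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value.

    Identical constant groups return ``(0.0, 1.0)``; zero within-group
    variance with unequal means leaves F undefined and raises.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_x = np.concatenate(gs)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b = len(gs) - 1
    df_w = all_x.size - len(gs)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        raise ValueError("zero within-group variance with unequal means: F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def linreg(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares: slope, intercept, R^2, slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        return 0.0, float(y.mean()), 0.0, 1.0
    res = sps.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )
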