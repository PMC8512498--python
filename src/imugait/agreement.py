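"""Between-algorithm agreement statistics.

For each temporal parameter and statistic the two algorithms yield one value
per subject; agreement across subjects is quantified with Pearson's r,
Spearman's rho, the single-measure absolute-agreement intraclass correlation
ICC(2,1) with its 95% CI and p-value (two-way ANOVA decomposition, F-based
interval of McGraw & Wong), a categorical agreement label, the absolute
difference of the two means (AD), Bland-Altman statistics, and an OLS
regression of one method on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    diffs: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))


@dataclass
class AgreementResult:
    """Full agreement record for one parameter/statistic cell."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    icc: ICCResult
    category: str
    ad_of_means: float
    bland_altman: BlandAltmanResult
    slope: float
    intercept: float
    n: int


def _validate_matrix(a1, a2, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("need two aligned 1-d columns of per-subject values")
    keep = np.isfinite(a1) & np.isfinite(a2)
    a1, a2 = a1[keep], a2[keep]
    if a1.size < min_n:
        raise ValueError(f"need at least {min_n} complete pairs, got {a1.size}")
    return a1, a2


def icc_2_1(a1, a2, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC from the two-way ANOVA model.

    With n subjects (rows) and k = 2 raters (the two algorithms)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    CI and p follow the F-based procedure of McGraw & Wong (1996) for
    ICC(A,1); the estimate may be negative.  A matrix with zero total
    variance is degenerate (raises) rather than reported as ICC = 1.
    """
    y1, y2 = _validate_matrix(a1, a2)
    n, k = y1.size, 2
    data = np.column_stack([y1, y2])
    if np.allclose(data, data.flat[0]):
        raise ValueError("degenerate matrix: zero total variance")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate matrix: zero denominator")
    icc = (msr - mse) / denom

    # McGraw & Wong F-based CI for ICC(A,1)
    if mse > 0:
        fj = msc / mse
        a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a):
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f_star_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = (n * (msr - f_star_u * mse)) / (
                f_star_u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = (n * (f_star_l * msr - mse)) / (
                k * msc + (k * n - k - n) * mse + n * f_star_l * msr
            )
        else:
            lower = upper = 1.0
        f_obs = msr / mse
        p = float(stats.f.sf(f_obs, n - 1, (n - 1) * (k - 1)))
    else:
        lower = upper = icc
        p = 0.0
    return ICCResult(float(icc), float(lower), float(upper), p)


def correlation_suite(a1, a2) -> tuple[float, float, float, float]:
    """Pearson r and Spearman rho (average ranks for ties), two-tailed p."""
    y1, y2 = _validate_matrix(a1, a2)
    if np.std(y1) == 0 or np.std(y2) == 0:
        raise ValueError("undefined correlation: a column has zero variance")
    pr = stats.pearsonr(y1, y2)
    sr = stats.spearmanr(y1, y2)
    return float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue)


def bland_altman(a1, a2, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Mean difference and limits of agreement of paired measurements."""
    y1, y2 = _validate_matrix(a1, a2, min_n=2)
    d = y1 - y2
    mean_diff = float(d.mean())
    sd_diff = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_lower=mean_diff - loa_multiplier * sd_diff,
        loa_upper=mean_diff + loa_multiplier * sd_diff,
        means=(y1 + y2) / 2.0,
        diffs=d,
    )


def absolute_difference(mean_a1: float, mean_a2: float) -> float:
    """AD = |A1 - A2| of the two algorithms' mean estimates."""
    if not (np.isfinite(mean_a1) and np.isfinite(mean_a2)):
        raise ValueError("absolute difference requires finite inputs")
    return abs(mean_a1 - mean_a2)


#: category bins as printed: <=0.30 none, 0.31-0.50 fair, 0.51-0.70 moderate,
#: 0.71-0.90 substantial, >=0.91 very good; gap values (e.g. 0.905) resolve
#: downward.
AGREEMENT_BINS = (
    (0.30, "none"),
    (0.50, "fair"),
    (0.70, "moderate"),
    (0.90, "substantial"),
    (1.00, "very_good"),
)


def classify_agreement(coefficient: float) -> str:
    """Categorical agreement label for a correlation-type coefficient."""
    if not -1.0 <= coefficient <= 1.0:
        raise ValueError(f"coefficient {coefficient} outside [-1, 1]")
    if coefficient >= 0.91 - 1e-12:
        return "very_good"
    for upper, label in AGREEMENT_BINS[:-1]:
        if coefficient <= upper + 1e-12:
            return label
    return "substantial"  # gap values in (0.90, 0.91) resolve downward


def agreement_suite(a1, a2) -> AgreementResult:
    """All agreement statistics for one pair of per-subject columns."""
    y1, y2 = _validate_matrix(a1, a2)
    pr, pp, rho, rp = correlation_suite(y1, y2)
    icc = icc_2_1(y1, y2)
    ba = bland_altman(y1, y2)
    reg = stats.linregress(y1, y2)
    return AgreementResult(
        pearson_r=pr,
        pearson_p=pp,
        spearman_rho=rho,
        spearman_p=rp,
        icc=icc,
        category=classify_agreement(icc.estimate),
        ad_of_means=absolute_difference(float(y1.mean()), float(y2.mean())),
        bland_altman=ba,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        n=int(y1.size),
    )
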