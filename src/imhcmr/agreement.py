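"""Inter-observer and inter-method agreement statistics.

ICC: two-way random-effects, absolute-agreement, single-measure — ICC(2,1) in
the Shrout-Fleiss taxonomy, ICC(A,1) in McGraw-Wong — computed from the
two-way ANOVA mean squares, with the F-distribution confidence interval of
McGraw & Wong.  Bland-Altman: bias as the mean of (reference - comparison)
differences, limits of agreement bias +/- 1.96 * sample SD.  Extent-vs-extent
comparisons use ordinary least squares with R^2 as the squared Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ICCResult", "BlandAltman", "Regression", "icc", "bland_altman", "extent_regression"]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float


@dataclass
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class Regression:
    slope: float
    intercept: float
    r_squared: float


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares of a two-way
    crossed design with one observation per cell."""
    n, k = data.shape
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
    return msr, msc, mse


def icc(pairs: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(2,1) with its F-based confidence interval.

    ``pairs`` is an (n_subjects, k_raters) matrix with no missing cells,
    n >= 3.  Returns NaN when the total variance is zero (agreement of
    constants is undefined).
    """
    data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an (n_subjects, k_raters >= 2) matrix")
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    if np.allclose(data, data.flat[0]):
        return ICCResult(float("nan"), float("nan"), float("nan"))

    msr, msc, mse = _anova_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return ICCResult(float("nan"), float("nan"), float("nan"))
    r = (msr - mse) / denom

    if mse == 0 and msc == 0:
        # perfect absolute agreement; the F construction degenerates
        return ICCResult(1.0, 1.0, 1.0)

    alpha = 1.0 - confidence
    a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = sps.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = float("nan")
    return ICCResult(icc=float(r), ci_low=float(lower), ci_high=float(upper))


def bland_altman(reference: np.ndarray, comparison: np.ndarray) -> BlandAltman:
    """Bias and 95% limits of agreement of paired measurements.

    Differences are (reference - comparison) — with bright-blood extent as the
    reference and dark-blood as the comparison, a positive bias means the
    dark-blood arm underestimates.  SD uses the n-1 divisor; limits are
    bias +/- 1.96 SD.
    """
    x = np.asarray(reference, dtype=float)
    y = np.asarray(comparison, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D arrays")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def extent_regression(x: np.ndarray, y: np.ndarray) -> Regression:
    """Ordinary least squares of y on x with R^2 = squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D arrays with n >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        return Regression(slope=0.0, intercept=float(y.mean()), r_squared=0.0)
    res = sps.linregress(x, y)
    return Regression(slope=float(res.slope), intercept=float(res.intercept),
                      r_squared=float(res.rvalue**2))
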