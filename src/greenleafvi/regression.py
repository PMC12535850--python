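"""Validation statistics: CVI-vs-chlorophyll regressions and correlations.

Chlorophyll content (y, mg/cm^2) is regressed on a CVI (x) with ordinary
least squares, ``y ~ x``.  The Woebbecke index relates hyperbolically to
chlorophyll, so it is fitted on the transformed predictor ``u = -1/x``
instead (``y ~ -1/x``).  Pearson correlation and a Bonferroni threshold
helper for multiple-testing arithmetic round out the module.  Pairs with a
missing (NaN) member are dropped listwise before fitting; p-values come
from the exact t distribution with n - 2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


class InsufficientDataError(ValueError):
    """Fewer than three finite (x, y) pairs remain after NA removal."""


class DegenerateDataError(ValueError):
    """Predictor or response has zero variance; the fit is ill-defined."""


@dataclass(frozen=True)
class RegressionFit:
    """Simple-regression summary: slope, intercept, R^2, slope-test p, n."""

    model: str  # "linear" | "reciprocal"
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 finite pairs, have {x.size}"
        )
    return x, y


def _ols(x: np.ndarray, y: np.ndarray, model: str) -> RegressionFit:
    if np.ptp(x) == 0:
        raise DegenerateDataError("predictor has zero variance")
    if np.ptp(y) == 0:
        raise DegenerateDataError("response has zero variance; R^2 is ill-defined")
    res = stats.linregress(x, y)
    return RegressionFit(
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def fit_linear(x, y) -> RegressionFit:
    """OLS of y on x; R^2 = 1 - SS_res/SS_tot, p from the slope t test."""
    x, y = _clean_pairs(x, y)
    return _ols(x, y, "linear")


def fit_reciprocal(x, y) -> RegressionFit:
    """OLS of y on the transformed predictor u = -1/x (hyperbolic relation).

    Any x exactly zero is a domain error: an UNDEFINED Woebbecke value must
    be dropped before fitting, not passed through as zero.
    """
    x, y = _clean_pairs(x, y)
    if np.any(x == 0):
        raise ValueError("x contains 0; -1/x is undefined there")
    return _ols(-1.0 / x, y, "reciprocal")


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation r and its two-sided t-test p-value."""
    x, y = _clean_pairs(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bonferroni_neglog10_threshold(alpha: float, m: int) -> float:
    """Family-wise significance cutoff -log10(alpha / m) across m tests."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return -math.log10(alpha / m)
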