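"""Robust statistics: one-step M-estimator, percentile bootstrap tests,
Hochberg step-up correction, Theil-Sen regression and outlier rules.

These primitives back the regional-dynamics comparisons.  The one-step
M-estimator starts from the median and applies a single Huber step with
tuning constant k = 1.28 on the MAD scale; paired comparisons use the
percentile bootstrap of the one-step estimate of the paired differences,
``p = 2 min(P, 1-P)`` with ``P`` the bootstrap fraction of positive
estimates.  Bivariate outliers can be trimmed by the MAD-median rule or the
projection method before a bootstrap Theil-Sen regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "onestep_m",
    "paired_percentile_bootstrap",
    "hochberg",
    "theil_sen_slope",
    "bootstrap_regression",
    "mad_median_outliers",
    "projection_outliers",
    "outlier_filter",
    "RobustTestResult",
    "RegressionResult",
]

HUBER_K = 1.28
MAD_SCALE = 1.4826
#: sqrt(chi^2_{0.975, 1}) = 2.2414; both outlier rules screen univariate
#: quantities (coordinates or projections), so the 1-dof quantile applies
OUTLIER_CUTOFF = float(np.sqrt(stats.chi2.ppf(0.975, 1)))


@dataclass
class RobustTestResult:
    comparison: str
    estimate: float
    p_raw: float
    p_adj: float | None = None
    B: int = 0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def onestep_m(x: np.ndarray, k: float = HUBER_K, axis: int = -1) -> np.ndarray:
    """One-step Huber M-estimator of location (vectorized along ``axis``).

    With M the median and MADN = 1.4826 * MAD, values beyond M +/- k*MADN are
    trimmed and re-entered through the Huber correction term:

    ``theta = (k * MADN * (i2 - i1) + sum of untrimmed values) / (n - i1 - i2)``
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=axis, keepdims=True)
    madn = MAD_SCALE * np.median(np.abs(x - med), axis=axis, keepdims=True)
    lo_mask = x < med - k * madn
    hi_mask = x > med + k * madn
    i1 = lo_mask.sum(axis=axis)
    i2 = hi_mask.sum(axis=axis)
    keep = ~(lo_mask | hi_mask)
    ssum = np.where(keep, x, 0.0).sum(axis=axis)
    denom = x.shape[axis] - i1 - i2
    madn_s = np.squeeze(madn, axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = (k * madn_s * (i2 - i1) + ssum) / denom
    # all values identical -> MAD 0, nothing trimmed, theta = mean = median
    return theta


def paired_percentile_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
    comparison: str = "",
) -> RobustTestResult:
    """Percentile bootstrap test of the one-step M-estimator of x - y.

    Rows are resampled jointly (paired design).  Two-sided p-value
    ``2 min(P, 1-P)`` where P is the bootstrap fraction of positive
    estimates (ties split evenly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boots = onestep_m(d[idx], axis=-1)
    p_hat = (np.count_nonzero(boots > 0) + 0.5 * np.count_nonzero(boots == 0)) / B
    p = 2.0 * min(p_hat, 1.0 - p_hat)
    return RobustTestResult(comparison, float(onestep_m(d)), float(min(p, 1.0)), B=B)


def hochberg(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="simes-hochberg")[1]


def theil_sen_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Theil-Sen estimator: median of all pairwise slopes; intercept is the
    median of ``y - slope * x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(len(x), k=1)
    dxu, dyu = dx[iu], dy[iu]
    finite = dxu != 0
    if not finite.any():
        raise ValueError("all x values identical")
    slope = float(np.median(dyu[finite] / dxu[finite]))
    intercept = float(np.median(y - slope * x))
    return slope, intercept


def bootstrap_regression(
    x: np.ndarray,
    y: np.ndarray,
    B: int = 10_000,
    seed: int = 0,
) -> RegressionResult:
    """Bootstrap Theil-Sen regression: slope, Pearson r of the points, and a
    two-sided percentile-bootstrap p-value for a nonzero slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 points")
    slope, intercept = theil_sen_slope(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        while len(np.unique(x[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        boots[b] = theil_sen_slope(x[idx], y[idx])[0]
    p_hat = (np.count_nonzero(boots > 0) + 0.5 * np.count_nonzero(boots == 0)) / B
    p = float(min(2.0 * min(p_hat, 1.0 - p_hat), 1.0))
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(slope, intercept, r, p, n)


def mad_median_outliers(points: np.ndarray, cutoff: float = OUTLIER_CUTOFF) -> np.ndarray:
    """Boolean keep-mask: drop a point when either standardized coordinate
    ``|x - median| / (1.4826 MAD)`` exceeds ``cutoff``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    keep = np.ones(pts.shape[0], dtype=bool)
    for j in range(pts.shape[1]):
        col = pts[:, j]
        med = np.median(col)
        madn = MAD_SCALE * np.median(np.abs(col - med))
        if madn == 0:
            import warnings

            warnings.warn(f"degenerate MAD in coordinate {j}; skipped")
            continue
        keep &= np.abs(col - med) / madn <= cutoff
    return keep


def projection_outliers(points: np.ndarray, cutoff: float = OUTLIER_CUTOFF) -> np.ndarray:
    """Projection-method keep-mask (approximated over the n center-to-point
    directions): a point is dropped when its projection onto any direction
    through the coordinate-wise median lies more than ``cutoff`` robust
    standard deviations from the projected median."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    center = np.median(pts, axis=0)
    rel = pts - center
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        norm = np.linalg.norm(rel[i])
        if norm == 0:
            continue
        direction = rel[i] / norm
        proj = rel @ direction
        med = np.median(proj)
        madn = MAD_SCALE * np.median(np.abs(proj - med))
        if madn == 0:
            continue
        keep &= np.abs(proj - med) / madn <= cutoff
    return keep


def outlier_filter(points: np.ndarray, rule: str = "mad_median") -> np.ndarray:
    """Keep-mask for bivariate points under the named rule."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points")
    if rule == "mad_median":
        return mad_median_outliers(pts)
    if rule == "projection":
        return projection_outliers(pts)
    raise ValueError(f"unknown outlier rule {rule!r}")
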