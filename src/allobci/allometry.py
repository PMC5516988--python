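"""Bivariate line fitting for allometric scaling analysis.

Implements the three classical line-fitting methods used in allometry:

* **OLS** (ordinary least squares, Type I): minimises vertical residuals,
  slope ``b = r * s_y / s_x``;
* **SMA** (standardized / reduced major axis, Type II): slope is the
  sign-adjusted ratio of standard deviations, ``b = sign(r) * s_y / s_x``;
* **MA** (major axis, Type II): the first principal axis of the sample
  covariance matrix.

All three lines pass through the centroid ``(mean x, mean y)``. Residuals
are always *vertical* (in the y direction) regardless of method, because
downstream body-condition indices interpret a residual as "observed minus
expected mass".

Also provides the likelihood-ratio test for a common SMA slope across
groups, the standard tool for asking whether two sexes (or handling
groups) share one allometric exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["AxisFit", "CommonSlopeTest", "fit_line", "residuals", "common_slope_test"]

_METHODS = ("OLS", "MA", "SMA")
_TRANSFORMS = ("identity", "log")


@dataclass(frozen=True)
class AxisFit:
    """A fitted straight line on (possibly log-transformed) axes.

    ``slope_ci`` is the two-sided confidence interval on the slope at level
    ``1 - alpha``. ``x_transform``/``y_transform`` record whether each axis
    was log-transformed before fitting; ``log_base`` is the base used
    (slopes, r and r² on log-log axes are invariant to the base).
    """

    method: str
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    slope_ci: tuple[float, float]
    alpha: float = 0.05
    x_transform: str = "identity"
    y_transform: str = "identity"
    log_base: float = math.e
    x_mean: float = float("nan")
    y_mean: float = float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted y on the fit's axes for x given on the fit's axes."""
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class CommonSlopeTest:
    """Result of the likelihood-ratio test for a common SMA slope.

    Under the null hypothesis that all ``k`` groups share one slope, the
    statistic is asymptotically chi-square with ``k - 1`` degrees of
    freedom.
    """

    statistic: float
    df: int
    p: float
    common_slope: float
    group_slopes: tuple[float, ...]
    k: int


def _apply_transform(v: np.ndarray, transform: str, base: float, axis: str) -> np.ndarray:
    if transform == "identity":
        return v
    if np.any(v <= 0):
        raise ValueError(f"log transform of {axis} requires strictly positive values")
    return np.log(v) / math.log(base)


def _moments(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("degenerate input: zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return mx, my, sx, sy, r


def _sma_ci(b: float, r: float, n: int, alpha: float) -> tuple[float, float]:
    # F-based interval: B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)
    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r * r) / (n - 2)
    lo = b * (math.sqrt(B + 1) - math.sqrt(B))
    hi = b * (math.sqrt(B + 1) + math.sqrt(B))
    return (min(lo, hi), max(lo, hi))


def _ols_ci(b: float, r: float, sx: float, sy: float, n: int, alpha: float) -> tuple[float, float]:
    se = math.sqrt(max(0.0, 1 - r * r) / (n - 2)) * sy / sx
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    return (b - t * se, b + t * se)


def _ma_ci(b: float, sx: float, sy: float, r: float, n: int, alpha: float) -> tuple[float, float]:
    # Jolicoeur (1968) eigenvalue-based interval, tangent-addition form.
    cov = r * sx * sy
    tr = sx * sx + sy * sy
    det = sx * sx * sy * sy - cov * cov
    disc = math.sqrt(max(0.0, tr * tr - 4 * det))
    l1 = (tr + disc) / 2  # principal eigenvalue
    l2 = (tr - disc) / 2
    if l2 <= 0 or l1 == l2:  # perfect line: zero-width interval
        return (b, b)
    t2 = stats.t.ppf(1 - alpha / 2, n - 2) ** 2
    H = t2 / ((l1 / l2 + l2 / l1 - 2) * (n - 2))
    if H >= 1:
        return (-math.inf, math.inf)
    A = math.sqrt(H / (1 - H))
    # limits are tan(atan(b) +/- atan(A))
    lo = (b - A) / (1 + b * A)
    hi = (b + A) / (1 - b * A) if b * A < 1 else math.inf
    return (min(lo, hi), max(lo, hi))


def fit_line(
    x,
    y,
    method: str = "SMA",
    alpha: float = 0.05,
    x_transform: str = "identity",
    y_transform: str = "identity",
    log_base: float = math.e,
) -> AxisFit:
    """Fit a straight line by OLS, MA or SMA.

    Parameters
    ----------
    x, y : array-like
        Paired observations, ``n >= 3``. When a transform is ``"log"``,
        the corresponding axis is log-transformed (base ``log_base``)
        before fitting, and all reported quantities live on the
        transformed axes.
    method : {"OLS", "MA", "SMA"}
    alpha : float
        The slope confidence interval has level ``1 - alpha``.

    Returns
    -------
    AxisFit

    Raises
    ------
    ValueError
        For fewer than 3 points, zero variance on either axis, or an MA
        fit with exactly zero correlation (slope undefined).
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    if x_transform not in _TRANSFORMS or y_transform not in _TRANSFORMS:
        raise ValueError(f"transforms must be one of {_TRANSFORMS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 points, got {n}")
    xt = _apply_transform(x, x_transform, log_base, "x")
    yt = _apply_transform(y, y_transform, log_base, "y")
    mx, my, sx, sy, r = _moments(xt, yt)

    if method == "OLS":
        b = r * sy / sx
        ci = _ols_ci(b, r, sx, sy, n, alpha)
    elif method == "SMA":
        if r == 0:
            # sign convention: SMA slope takes the sign of r; r = 0 leaves it undefined
            raise ValueError("SMA slope sign undefined at r = 0")
        b = math.copysign(sy / sx, r)
        ci = _sma_ci(b, r, n, alpha)
    else:  # MA
        if r == 0:
            raise ValueError("MA slope undefined at r = 0")
        sy2, sx2 = sy * sy, sx * sx
        cov = r * sx * sy
        b = (sy2 - sx2 + math.sqrt((sy2 - sx2) ** 2 + 4 * cov * cov)) / (2 * cov)
        ci = _ma_ci(b, sx, sy, r, n, alpha)

    return AxisFit(
        method=method,
        slope=b,
        intercept=my - b * mx,
        r=r,
        r2=r * r,
        n=n,
        slope_ci=ci,
        alpha=alpha,
        x_transform=x_transform,
        y_transform=y_transform,
        log_base=log_base,
        x_mean=mx,
        y_mean=my,
    )


def residuals(fit: AxisFit, x, y) -> np.ndarray:
    """Vertical residuals ``y - (a + b*x)`` on the fit's (possibly log) axes.

    ``x`` and ``y`` are given on the *original* scale; the fit's recorded
    transforms are applied before differencing. When ``x, y`` are the data
    the line was fitted to, the residuals sum to zero (all three methods
    pass through the centroid).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xt = _apply_transform(x, fit.x_transform, fit.log_base, "x")
    yt = _apply_transform(y, fit.y_transform, fit.log_base, "y")
    return yt - fit.predict(xt)


def _lr_statistic(b: float, groups: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """-sum_i n_i * ln(1 - r_i(b)^2) with r_i the correlation of the
    residual axis u = y - b*x with the major axis v = y + b*x within group i.
    Zero iff every group's SMA slope equals b."""
    total = 0.0
    for xt, yt in groups:
        u = yt - b * xt
        v = yt + b * xt
        su = np.std(u, ddof=1)
        sv = np.std(v, ddof=1)
        if su == 0 or sv == 0:
            continue  # group fits b exactly; contributes 0
        r = float(np.corrcoef(u, v)[0, 1])
        r2 = min(r * r, 1 - 1e-15)
        total += -len(xt) * math.log1p(-r2)
    return total


def common_slope_test(
    groups,
    alpha: float = 0.05,
    x_transform: str = "identity",
    y_transform: str = "identity",
    log_base: float = math.e,
) -> CommonSlopeTest:
    """Likelihood-ratio test that several groups share one SMA slope.

    The common slope is found by 1-D bounded minimisation of the LR
    statistic over ``b``; the bracket spans [min group slope / 3,
    max group slope * 3] (sign-adjusted). The statistic at the minimiser
    is referred to a chi-square distribution with ``k - 1`` df.

    Parameters
    ----------
    groups : sequence of (x, y) pairs
        ``k >= 2`` groups, each with ``n >= 3`` paired observations on the
        original scale; transforms are applied per ``fit_line``.

    Returns
    -------
    CommonSlopeTest
    """
    if len(groups) < 2:
        raise ValueError(f"need k >= 2 groups, got {len(groups)}")
    fits = [
        fit_line(x, y, "SMA", alpha, x_transform, y_transform, log_base)
        for x, y in groups
    ]
    slopes = [f.slope for f in fits]
    signs = {math.copysign(1, b) for b in slopes}
    if len(signs) > 1:
        raise ValueError(
            "group SMA slopes have mixed signs; no meaningful common slope"
        )
    sign = signs.pop()
    transformed = []
    for x, y in groups:
        xt = _apply_transform(np.asarray(x, dtype=float), x_transform, log_base, "x")
        yt = _apply_transform(np.asarray(y, dtype=float), y_transform, log_base, "y")
        transformed.append((xt, yt))

    mags = [abs(b) for b in slopes]
    lo, hi = min(mags) / 3.0, max(mags) * 3.0
    res = optimize.minimize_scalar(
        lambda m: _lr_statistic(sign * m, transformed),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"common-slope optimisation failed: {res.message}")
    b_hat = sign * float(res.x)
    statistic = max(0.0, float(res.fun))
    k = len(groups)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return CommonSlopeTest(
        statistic=statistic,
        df=df,
        p=p,
        common_slope=b_hat,
        group_slopes=tuple(slopes),
        k=k,
    )
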