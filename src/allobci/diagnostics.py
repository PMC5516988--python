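"""Rank statistics and regression-assumption diagnostics.

Kendall's tau-b and the Mann-Whitney U test carry the accuracy/bias
assessment; the regression battery (Ramsey RESET for linearity,
studentised Breusch-Pagan for homoscedasticity, Shapiro-Wilk plus the
D'Agostino skewness and Anscombe-Glynn kurtosis tests for residual
normality) checks the assumptions behind residual-based condition
indices. The size-bias partition splits a stratum into two length classes
flanking the mean SVL.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan, linear_reset

from .data_model import Stratum

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "TestResult",
    "AssumptionReport",
    "kendall_tau",
    "mann_whitney",
    "size_partition",
    "regression_assumptions",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Kendall rank correlation (tau-b) with pair-count bookkeeping.

    ``n_ties_x``/``n_ties_y`` count pairs tied only in that variable;
    ``n_ties_xy`` counts pairs tied in both (these enter neither the
    numerator nor the tie correction).
    """

    tau: float
    p: float
    n: int
    n_concordant: int
    n_discordant: int
    n_ties_x: int
    n_ties_y: int
    n_ties_xy: int


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney result under the U-of-the-first-sample convention.

    ``w`` counts pairs ``(a_i, b_j)`` with ``a_i > b_j`` plus half the
    cross-group ties, so ``0 <= w <= n1 * n2`` and swapping the groups
    maps ``w`` to ``n1*n2 - w``.
    """

    w: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "normal_approx"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float


@dataclass(frozen=True)
class AssumptionReport:
    """Regression assumption battery for one (x, y) pair.

    The moment tests (skewness, kurtosis) follow the reporting convention
    of applying them only once normality is rejected; they are ``None``
    when not run. Point estimates of sample skewness and excess kurtosis
    are always included.
    """

    reset: TestResult
    breusch_pagan: TestResult
    shapiro_wilk: TestResult
    dagostino_skew: TestResult | None
    anscombe_glynn_kurtosis: TestResult | None
    skewness: float
    excess_kurtosis: float
    n: int


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, int]:
    # O(n^2) vectorised pair classification; n here is at most a few thousand
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    dx, dy = dx[iu], dy[iu]
    s = dx * dy
    conc = int(np.sum(s > 0))
    disc = int(np.sum(s < 0))
    tx = int(np.sum((dx == 0) & (dy != 0)))
    ty = int(np.sum((dy == 0) & (dx != 0)))
    txy = int(np.sum((dx == 0) & (dy == 0)))
    return conc, disc, tx, ty, txy


def kendall_tau(x, y) -> CorrelationResult:
    """Kendall's tau-b between two equally long vectors.

    The two-sided p-value uses the tie-corrected normal approximation
    (exact enumeration for small untied samples). Constant input leaves
    tau undefined and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for a constant vector")
    res = stats.kendalltau(x, y)
    conc, disc, tx, ty, txy = _pair_counts(x, y)
    # tau-b from the integer pair counts: exact at the +/-1 boundaries,
    # where the accumulation-based estimate can be off by one ulp
    n0 = x.size * (x.size - 1) // 2
    tau = (conc - disc) / math.sqrt((n0 - tx - txy) * (n0 - ty - txy))
    return CorrelationResult(
        tau=float(tau),
        p=float(res.pvalue),
        n=x.size,
        n_concordant=conc,
        n_discordant=disc,
        n_ties_x=tx,
        n_ties_y=ty,
        n_ties_xy=txy,
    )


def mann_whitney(a, b) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact two-sided p when the pooled sample has at most 20 observations
    and no cross-sample ties; otherwise the normal approximation with
    continuity and tie corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    exact = (a.size + b.size) <= 20 and no_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return RankTestResult(
        w=float(res.statistic),
        p=float(res.pvalue),
        n1=a.size,
        n2=b.size,
        method="exact" if exact else "normal_approx",
    )


def size_partition(
    stratum: Stratum, values, window_cm: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-record values into two length classes flanking the mean SVL.

    The low class holds records with ``mean - window <= svl < mean``, the
    high class those with ``mean < svl <= mean + window``; records exactly
    at the mean are excluded so the classes are disjoint. The default
    25 cm window makes two adjacent 0.25 m bands, so members of opposite
    classes differ in SVL by at most 0.5 m.

    Parameters
    ----------
    stratum : Stratum
    values : array-like
        One value per record, in stratum order (e.g. a BCI column).
    window_cm : float
        Band width on each side of the mean, in cm.

    Returns
    -------
    (low, high) : pair of arrays of values.
    """
    values = np.asarray(values, dtype=float)
    svl = np.asarray(stratum.column("svl"), dtype=float)
    if values.shape != svl.shape:
        raise ValueError(
            f"expected one value per record ({svl.size}), got {values.size}"
        )
    mean = svl.mean()
    low = values[(svl >= mean - window_cm) & (svl < mean)]
    high = values[(svl > mean) & (svl <= mean + window_cm)]
    if low.size == 0 or high.size == 0:
        raise ValueError(
            f"empty size class below/above mean SVL {mean:.1f} cm within "
            f"{window_cm} cm; widen the window"
        )
    return low, high


def regression_assumptions(
    x, y, resid=None, moment_tests: str = "auto"
) -> AssumptionReport:
    """Test linearity, homoscedasticity and residual normality of y on x.

    RESET augments the OLS fit of y on x with fitted-value powers 2 and 3
    and F-tests their joint contribution; Breusch-Pagan is the studentised
    (Koenker) variant against variance depending on x; Shapiro-Wilk,
    D'Agostino skewness and Anscombe-Glynn kurtosis act on the residuals.

    Parameters
    ----------
    x, y : array-like, n >= 10.
    resid : array-like, optional
        Residuals to subject to the normality tests; defaults to the OLS
        residuals. Pass e.g. MA or SMA residuals to check a Type-II fit's
        error distribution while keeping RESET/BP on the OLS scaffold.
    moment_tests : {"auto", "always"}
        ``"auto"`` runs the skewness/kurtosis tests only when Shapiro-Wilk
        rejects at 0.05; ``"always"`` runs them unconditionally.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need paired vectors with n >= 10")
    if moment_tests not in ("auto", "always"):
        raise ValueError("moment_tests must be 'auto' or 'always'")

    exog = sm.add_constant(x)
    ols = sm.OLS(y, exog).fit()
    reset_res = linear_reset(ols, power=3, test_type="fitted", use_f=True)
    reset = TestResult(float(reset_res.fvalue), float(reset_res.pvalue))
    lm, lm_p, _, _ = het_breuschpagan(ols.resid, exog, robust=True)
    bp = TestResult(float(lm), float(lm_p))

    e = ols.resid if resid is None else np.asarray(resid, dtype=float)
    sw_stat, sw_p = stats.shapiro(e)
    sw = TestResult(float(sw_stat), float(sw_p))

    run_moments = moment_tests == "always" or sw.p <= 0.05
    skew_t = kurt_t = None
    if run_moments:
        zs, ps = stats.skewtest(e)
        zk, pk = stats.kurtosistest(e)
        skew_t = TestResult(float(zs), float(ps))
        kurt_t = TestResult(float(zk), float(pk))

    return AssumptionReport(
        reset=reset,
        breusch_pagan=bp,
        shapiro_wilk=sw,
        dagostino_skew=skew_t,
        anscombe_glynn_kurtosis=kurt_t,
        skewness=float(stats.skew(e)),
        excess_kurtosis=float(stats.kurtosis(e)),
        n=x.size,
    )
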