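"""Trend estimation for short annual series of reburn proportions.

Two estimators: the Theil-Sen slope (median of all pairwise slopes — robust
for short, noisy series) with the classical rank-based confidence interval
and a bootstrap standard error, and weighted least squares for the
cover-composition trend.  Before trend estimation the series can be checked
for short-term serial autocorrelation with the Box-Pierce portmanteau test
(Q = n * sum of squared lag-k autocorrelations, chi-square reference); the
check is advisory — a failure is logged, the trend is still computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_REPS = 2_000
#: Two-sided confidence level of the reported ci_lo/ci_hi (5th/95th bounds).
CONFIDENCE = 0.90


@dataclass(frozen=True)
class AutocorrResult:
    Q: float
    lags: int
    p_value: float
    n: int


@dataclass(frozen=True)
class TrendEstimate:
    slope: float
    intercept: float
    se: float
    ci_lo: float
    ci_hi: float
    method: str  # "theil_sen" | "wls"
    n: int
    r2: float | None = None
    F: float | None = None
    p: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def box_pierce(series, lags: int | None = None) -> AutocorrResult:
    """Box-Pierce test of short-term autocorrelation.

    Default number of lags is min(10, n // 5).  Constant series have
    undefined autocorrelation and raise.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if lags is None:
        lags = max(1, min(10, n // 5))
    if not n > lags >= 1:
        raise ValueError(f"require n > lags >= 1 (n={n}, lags={lags})")
    if np.ptp(x) == 0:
        raise ValueError("constant series: autocorrelation undefined")
    res = acorr_ljungbox(x, lags=[lags], boxpierce=True)
    return AutocorrResult(
        Q=float(res["bp_stat"].iloc[0]),
        lags=lags,
        p_value=float(res["bp_pvalue"].iloc[0]),
        n=n,
    )


def theil_sen(
    x,
    y,
    bootstrap_reps: int = DEFAULT_BOOTSTRAP_REPS,
    seed: int = 0,
    check_autocorr: bool = True,
) -> TrendEstimate:
    """Theil-Sen trend: slope = median over all pairwise slopes
    (y_j - y_i)/(x_j - x_i); intercept = median(y - slope*x).

    The 5th/95th confidence bounds come from the classical Sen rank-based
    procedure on the ordered pairwise slopes; the standard error from a
    seeded pair-resampling bootstrap.  Pairs with tied x are skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all x values equal")
    if check_autocorr and np.ptp(y) > 0:
        ac = box_pierce(y)
        if ac.p_value < 0.05:
            logger.warning(
                "Box-Pierce detects autocorrelation (Q=%.3f, p=%.4f); "
                "trend estimated regardless", ac.Q, ac.p_value,
            )
    res = stats.theilslopes(y, x, alpha=CONFIDENCE, method="separate")
    rng = np.random.default_rng(seed)
    boot = np.empty(bootstrap_reps)
    for b in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0:
            boot[b] = np.nan
            continue
        boot[b] = stats.theilslopes(yb, xb).slope
    se = float(np.nanstd(boot, ddof=1))
    return TrendEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        se=se,
        ci_lo=float(res.low_slope),
        ci_hi=float(res.high_slope),
        method="theil_sen",
        n=n,
    )


def weighted_linreg(x, y, w=None) -> TrendEstimate:
    """Weighted least-squares trend with weighted r-squared, F and p for
    the slope ((1, n-2) df).  Equal weights reduce to OLS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    keep = w > 0
    x, y, w = x[keep], y[keep], w[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points with positive weight")
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    lo, hi = model.conf_int(alpha=1 - CONFIDENCE)[1]
    return TrendEstimate(
        slope=slope,
        intercept=float(model.params[0]),
        se=se,
        ci_lo=float(lo),
        ci_hi=float(hi),
        method="wls",
        n=n,
        r2=float(model.rsquared),
        F=float(model.fvalue),
        p=float(model.f_pvalue),
    )
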