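"""Trial-level surrogacy: patient-weighted regression, R2 CI, classification.

The core computation regresses trial-specific treatment effects on the
final endpoint (log-OR of death) against effects on the candidate
surrogate (log-OR of bleeding), weighting each comparison by its
randomized patients.  Surrogacy strength is summarized by the
coefficient of determination R2 of that regression, its delta-method
confidence interval, and threshold labels under two published schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm, t as t_dist

from .errors import (DegenerateDesignError, InsufficientPairsError,
                     UndefinedStatisticError)

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "SurrogacyResult",
    "weighted_regression",
    "r2_confidence_interval",
    "classify_surrogacy",
    "format_regression",
]

#: Minimum pairs for the delta-method R2 CI (denominator n - 3 must be > 0).
MIN_PAIRS_FOR_CI = 4


@dataclass
class RegressionFit:
    """Weighted least-squares fit of y on x with an intercept."""

    n: int
    slope: float
    intercept: float
    r2: float
    slope_se: Optional[float]
    slope_ci: Optional[tuple]
    sigma2: Optional[float]  # weighted residual mean square, df = n - 2
    residuals: np.ndarray

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class SurrogacyResult:
    """Summary of one surrogate/final endpoint pairing."""

    surrogate_endpoint: str
    final_endpoint: str
    n_pairs: int
    n_trials: int
    n_patients: int
    slope: float
    slope_ci: Optional[tuple]
    intercept: float
    r2: float
    r2_ci: Optional[tuple]
    label_ci_scheme: str
    label_point_scheme: str
    formula_text: str


def _as_xyw(pairs) -> tuple:
    arr = np.asarray([(p[0], p[1], p[2]) for p in pairs], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("pairs must be (x, y, w) triples")
    return arr[:, 0], arr[:, 1], arr[:, 2]


def weighted_regression(pairs: Sequence, ci_level: float = 0.95) -> RegressionFit:
    """Weighted least squares of final-endpoint effects on surrogate effects.

    slope = sum w (x - xbar)(y - ybar) / sum w (x - xbar)^2 with weighted
    means, intercept = ybar - slope * xbar, and
    R2 = 1 - sum w (y - yhat)^2 / sum w (y - ybar)^2.  The slope CI uses
    a t quantile with n - 2 degrees of freedom and the weighted residual
    mean square; it needs n >= 3.  Results are invariant to rescaling
    all weights by a positive constant.
    """
    x, y, w = _as_xyw(pairs)
    n = len(x)
    if n < 2:
        raise InsufficientPairsError(f"need at least 2 pairs, got {n}")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise DegenerateDesignError("all surrogate effects identical")
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    rss = (w * resid ** 2).sum()
    tss = (w * (y - ybar) ** 2).sum()
    if tss <= 0:
        raise UndefinedStatisticError("all final-endpoint effects identical; "
                                      "R2 undefined")
    r2 = min(1.0, max(0.0, 1.0 - rss / tss))
    slope_se = slope_ci = sigma2 = None
    if n >= 3:
        sigma2 = rss / (n - 2)
        slope_se = math.sqrt(sigma2 / sxx)
        tq = t_dist.ppf(0.5 + ci_level / 2, n - 2)
        slope_ci = (slope - tq * slope_se, slope + tq * slope_se)
    return RegressionFit(n=n, slope=slope, intercept=intercept, r2=r2,
                         slope_se=slope_se, slope_ci=slope_ci, sigma2=sigma2,
                         residuals=resid)


def r2_confidence_interval(r2: float, n_pairs: int,
                           level: float = 0.95) -> Optional[tuple]:
    """Delta-method confidence interval for the trial-level R2.

    sd = sqrt(4 R2 (1 - R2)^2 / (n - 3)); the interval is
    R2 +/- z * sd clipped to [0, 1], with z the standard-normal quantile
    at (1 + level) / 2.  Requires at least 4 pairs; below that the
    point estimate stands alone and None is returned with a warning.
    """
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must lie in [0, 1], got {r2}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if n_pairs < MIN_PAIRS_FOR_CI:
        logger.warning("R2 CI needs >= %d pairs, got %d; CI omitted",
                       MIN_PAIRS_FOR_CI, n_pairs)
        return None
    sd = math.sqrt(4.0 * r2 * (1.0 - r2) ** 2 / (n_pairs - 3))
    z = norm.ppf(0.5 + level / 2.0)
    return (max(0.0, r2 - z * sd), min(1.0, r2 + z * sd))


def classify_surrogacy(r2: float, r2_ci: Optional[tuple]) -> tuple:
    """Surrogacy labels under the CI-based and point-estimate schemes.

    CI scheme: lower bound > 0.72 -> strong; upper bound < 0.50 -> weak;
    otherwise inconclusive (also when the CI is unavailable).
    Point scheme: R2 >= 0.7 -> strong; 0.5 <= R2 < 0.7 -> moderate;
    R2 < 0.5 -> weak.
    """
    if r2_ci is None:
        label_ci = "inconclusive"
        logger.warning("missing R2 CI; CI-scheme label set to inconclusive")
    else:
        lo, hi = r2_ci
        if lo > hi:
            raise ValueError(f"invalid CI ({lo}, {hi})")
        if lo > 0.72:
            label_ci = "strong"
        elif hi < 0.50:
            label_ci = "weak"
        else:
            label_ci = "inconclusive"
    if r2 >= 0.7:
        label_point = "strong"
    elif r2 >= 0.5:
        label_point = "moderate"
    else:
        label_point = "weak"
    return label_ci, label_point


def _round2(value: float) -> float:
    # normalize -0.0 so "-0.00" never renders
    return round(value, 2) + 0.0


def format_regression(intercept: float, slope: float,
                      surrogate_label: str = "bleeding") -> str:
    """Two-decimal regression formula, e.g. ``-0.06 + 0.14*log(OR_bleeding)``.

    A negative slope absorbs its sign into the operator:
    ``-0.09 - 0.11*log(OR_bleeding)``.
    """
    if not (math.isfinite(intercept) and math.isfinite(slope)):
        raise ValueError("intercept and slope must be finite")
    b0 = _round2(intercept)
    b1 = _round2(slope)
    op = "+" if b1 >= 0 else "-"
    return f"{b0:.2f} {op} {abs(b1):.2f}*log(OR_{surrogate_label})"
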