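"""Inverse-variance pooling with Cochran's Q, DerSimonian-Laird tau2, I2.

Between-study heterogeneity of each endpoint's treatment effects is
summarized by Cochran's Q, the method-of-moments (DerSimonian-Laird)
between-study variance tau2 truncated at zero, and
I2 = max(0, (Q - df) / Q) * 100.  Random-effects pooling (the default)
re-weights by 1 / (se_i^2 + tau2); with tau2 = 0 it coincides with the
fixed-effects estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import InsufficientPairsError, ValidationError

__all__ = ["HeterogeneityResult", "FunnelData", "pool_effects", "funnel_data"]


@dataclass
class HeterogeneityResult:
    """Pooled effect and heterogeneity statistics for one endpoint."""

    endpoint: Optional[str]
    k: int
    model: str  # fixed | random_dl
    pooled_log_effect: float
    pooled_se: float
    pooled_ci: tuple
    q: float
    df: int
    tau2: float
    i2_percent: float


@dataclass
class FunnelData:
    """Substrate for a funnel plot: (log effect, se) points and centerline."""

    points: list  # (log_effect, se, comparison_id), sorted by se ascending
    center: float  # fixed-effects pooled estimate


def _check_estimates(estimates: Sequence) -> tuple:
    theta, se = [], []
    for est in estimates:
        if not est.informative:
            continue
        if est.se is None or est.se <= 0:
            raise ValidationError(
                f"{est.comparison_id}: missing or non-positive standard error")
        theta.append(est.log_effect)
        se.append(est.se)
    return np.asarray(theta, float), np.asarray(se, float)


def pool_effects(estimates: Sequence, model: str = "random_dl",
                 ci_level: float = 0.95) -> HeterogeneityResult:
    """Pool per-comparison log effects under a fixed or random-effects model."""
    if model not in ("fixed", "random_dl"):
        raise ValueError(f"unknown model {model!r}")
    theta, se = _check_estimates(estimates)
    k = len(theta)
    if k < 2:
        raise InsufficientPairsError(f"need at least 2 informative studies, got {k}")
    w = 1.0 / se ** 2
    fixed = (w * theta).sum() / w.sum()
    q = float((w * (theta - fixed) ** 2).sum())
    df = k - 1
    denom = w.sum() - (w ** 2).sum() / w.sum()
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    if model == "fixed":
        pooled, pooled_se = fixed, float(np.sqrt(1.0 / w.sum()))
    else:
        w_re = 1.0 / (se ** 2 + tau2)
        pooled = float((w_re * theta).sum() / w_re.sum())
        pooled_se = float(np.sqrt(1.0 / w_re.sum()))
    z = norm.ppf(0.5 + ci_level / 2.0)
    endpoint = next((e.endpoint.value for e in estimates
                     if getattr(e, "endpoint", None) is not None), None)
    return HeterogeneityResult(
        endpoint=endpoint, k=k, model=model,
        pooled_log_effect=float(pooled), pooled_se=pooled_se,
        pooled_ci=(pooled - z * pooled_se, pooled + z * pooled_se),
        q=q, df=df, tau2=float(tau2), i2_percent=float(i2))


def funnel_data(estimates: Sequence) -> FunnelData:
    """Points (log effect, se) sorted by precision plus the fixed centerline."""
    informative = [e for e in estimates if e.informative and e.se is not None]
    if not informative:
        raise InsufficientPairsError("no informative estimates for funnel plot")
    if len(informative) == 1:
        center = informative[0].log_effect
    else:
        center = pool_effects(informative, model="fixed").pooled_log_effect
    points = sorted(((e.log_effect, e.se, e.comparison_id) for e in informative),
                    key=lambda p: p[1])
    return FunnelData(points=points, center=center)
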