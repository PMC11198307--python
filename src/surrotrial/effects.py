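"""Log-scale treatment-effect estimates from 2x2 tables or reported values.

Effects are expressed as natural-log odds ratios (or log hazard ratios
for the sensitivity track), with Woolf standard errors from the 2x2
cell counts and the total randomized patients carried along as the
analysis weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

from scipy.stats import norm

from .errors import InsufficientPairsError, ValidationError
from .trial_data import Endpoint, TrialComparison

logger = logging.getLogger(__name__)

__all__ = [
    "EffectEstimate",
    "EffectPair",
    "odds_ratio",
    "effect_from_reported",
    "build_pairs",
]


@dataclass
class EffectEstimate:
    """A log-scale relative effect with its standard error and weight.

    ``informative`` is false for the double-zero sentinel (no events in
    either arm): such comparisons carry no information about the odds
    ratio and are excluded downstream.
    """

    comparison_id: str
    endpoint: Optional[Endpoint]
    estimand: str  # or_from_counts | or_reported | hr_reported
    log_effect: float
    se: Optional[float]
    n_total: int
    correction_applied: bool = False
    informative: bool = True


class EffectPair(NamedTuple):
    """One point of the surrogate-vs-final scatter."""

    x: float  # log effect on the surrogate endpoint
    y: float  # log effect on the final endpoint
    w: float  # analysis weight (randomized patients)
    comparison_id: str


def odds_ratio(treat_events: int, n_treat: int, control_events: int,
               n_control: int, *, comparison_id: str = "",
               endpoint: Optional[Endpoint] = None,
               zero_cell: str = "haldane") -> EffectEstimate:
    """Log odds ratio and Woolf SE from per-arm events and arm sizes.

    With ``a`` events / ``b`` non-events in the treatment arm and ``c`` /
    ``d`` in control, the estimate is ``ln(ad/bc)`` with standard error
    ``sqrt(1/a + 1/b + 1/c + 1/d)``.  If any cell is zero and
    ``zero_cell='haldane'``, 0.5 is added to all four cells
    (Haldane-Anscombe) before both computations; ``zero_cell='exclude'``
    instead returns a non-informative sentinel.  A table with zero events
    in both arms is always non-informative.
    """
    if zero_cell not in ("haldane", "exclude"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
    if n_treat <= 0 or n_control <= 0:
        raise ValidationError(f"{comparison_id}: arm sizes must be positive")
    if not (0 <= treat_events <= n_treat):
        raise ValidationError(
            f"{comparison_id}: treat_events {treat_events} outside [0, {n_treat}]")
    if not (0 <= control_events <= n_control):
        raise ValidationError(
            f"{comparison_id}: control_events {control_events} outside [0, {n_control}]")

    n_total = n_treat + n_control
    a, b = float(treat_events), float(n_treat - treat_events)
    c, d = float(control_events), float(n_control - control_events)

    def sentinel() -> EffectEstimate:
        return EffectEstimate(comparison_id, endpoint, "or_from_counts",
                              math.nan, None, n_total, False, informative=False)

    if a == 0 and c == 0:
        logger.warning("%s: no events in either arm; non-informative", comparison_id)
        return sentinel()
    has_zero = 0.0 in (a, b, c, d)
    if has_zero and zero_cell == "exclude":
        logger.warning("%s: zero cell excluded under 'exclude' policy", comparison_id)
        return sentinel()
    if has_zero:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_effect = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(comparison_id, endpoint, "or_from_counts",
                          log_effect, se, n_total, correction_applied=has_zero)


def effect_from_reported(value: float, lo: Optional[float], hi: Optional[float],
                         estimand: str, *, comparison_id: str = "",
                         endpoint: Optional[Endpoint] = None,
                         n_total: int = 0) -> EffectEstimate:
    """Log effect (and SE back-calculated from the 95% CI) of a reported OR/HR.

    ``se = (ln hi - ln lo) / (2 z_0.975)``; when no CI was reported the
    SE is missing.  A degenerate CI (``lo == hi``) is rejected because
    the implied SE of zero is unusable.
    """
    if estimand not in ("or_reported", "hr_reported"):
        raise ValueError(f"unknown estimand {estimand!r}")
    if value is None or value <= 0:
        raise ValidationError(f"{comparison_id}: reported effect must be positive")
    se = None
    if lo is not None or hi is not None:
        if lo is None or hi is None or lo <= 0:
            raise ValidationError(f"{comparison_id}: CI must give both positive bounds")
        if not (lo <= value <= hi):
            raise ValidationError(
                f"{comparison_id}: CI ({lo}, {hi}) does not bracket {value}")
        se = (math.log(hi) - math.log(lo)) / (2 * norm.ppf(0.975))
        if se <= 0:
            raise ValidationError(f"{comparison_id}: degenerate CI implies se = 0")
    return EffectEstimate(comparison_id, endpoint, estimand,
                          math.log(value), se, n_total)


def estimate_for_endpoint(record: TrialComparison, endpoint: Endpoint,
                          zero_cell: str = "haldane") -> Optional[EffectEstimate]:
    """Count-based log-OR for one endpoint of one comparison, or None if absent."""
    pair = record.events.get(endpoint)
    if pair is None:
        return None
    return odds_ratio(pair[0], record.n_treat, pair[1], record.n_control,
                      comparison_id=record.comparison_id, endpoint=endpoint,
                      zero_cell=zero_cell)


def _final_effect(record: TrialComparison, endpoint: Endpoint,
                  estimand_policy: str, zero_cell: str) -> Optional[EffectEstimate]:
    if estimand_policy == "or_from_counts":
        return estimate_for_endpoint(record, endpoint, zero_cell)
    if estimand_policy == "hr_reported":
        # Sensitivity track: restrict to articles reporting a mortality HR.
        if record.reported_hr is None:
            return None
        lo, hi = record.reported_hr_ci or (None, None)
        return effect_from_reported(record.reported_hr, lo, hi, "hr_reported",
                                    comparison_id=record.comparison_id,
                                    endpoint=endpoint, n_total=record.n_total)
    raise ValueError(f"unknown estimand_policy {estimand_policy!r}")


def build_pairs(records: list, surrogate_endpoint: Endpoint,
                final_endpoint: Endpoint, estimand_policy: str = "or_from_counts",
                zero_cell: str = "haldane", min_pairs: int = 2) -> list:
    """Assemble (x, y, weight) scatter points for one endpoint pairing.

    ``x`` is the log-OR on the surrogate (bleeding) endpoint computed
    from counts; ``y`` is the log effect on the final (mortality)
    endpoint, from counts or — under the ``hr_reported`` policy — from
    the article's reported hazard ratio.  Comparisons missing either
    endpoint, or non-informative on either (double-zero tables), are
    excluded.  Order follows the input order.
    """
    if surrogate_endpoint == final_endpoint:
        raise ValueError("surrogate and final endpoints must differ")
    pairs = []
    for rec in records:
        sx = estimate_for_endpoint(rec, surrogate_endpoint, zero_cell)
        sy = _final_effect(rec, final_endpoint, estimand_policy, zero_cell)
        if sx is None or sy is None or not sx.informative or not sy.informative:
            continue
        pairs.append(EffectPair(sx.log_effect, sy.log_effect,
                                float(rec.n_total), rec.comparison_id))
    if len(pairs) < min_pairs:
        raise InsufficientPairsError(
            f"only {len(pairs)} informative pair(s) for "
            f"{surrogate_endpoint.value} vs {final_endpoint.value} "
            f"(need >= {min_pairs})")
    return pairs
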