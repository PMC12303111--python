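"""Deployment-time planning from camera-trap interaction logs.

How long must a tagging gate stay in the field before a target animal is
likely to present itself for tagging?  With P_s the per-hour probability
that the animal is within tagging distance of the gate, the cumulative
probability of at least one opportunity over t hours is geometric:

    P_Tag(t) = 1 − (1 − P_s)^t

P_s is estimated directly from camera-trap data as events-within-tagging-
distance per deployed hour.  The module also inverts the curve for the
deployment time needed to reach a target probability, and compares event
rates (e.g. baited vs unbaited gates) with a two-sample Poisson test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeploymentWindow",
    "TagProbabilityCurve",
    "HoursToTarget",
    "RateRatioResult",
    "estimate_ps",
    "p_tag",
    "probability_curve",
    "time_to_probability",
    "rate_ratio_test",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 30.5 h displays as 31 h, not 30)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class DeploymentWindow:
    """A deployment interval for one site."""

    site: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2


@dataclass(frozen=True)
class TagProbabilityCurve:
    """Cumulative tagging-opportunity probability over deployment hours."""

    p_s: float
    times: np.ndarray
    p_tag: np.ndarray


class HoursToTarget(NamedTuple):
    hours: float
    hours_rounded: int


@dataclass(frozen=True)
class RateRatioResult:
    """Two-sample Poisson rate comparison (A vs B)."""

    rate_a: float
    rate_b: float
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    z: float


def estimate_ps(
    events: pd.DataFrame, window: DeploymentWindow, species: str
) -> float:
    """Per-hour tagging-opportunity probability from an interaction log.

    Counts the species' events flagged within tagging distance that fall
    inside the window, divided by the deployed hours.  Repeat visits count
    as independent events (camera data cannot generally distinguish
    individuals).  Raises if the rate reaches 1.0: the geometric model
    needs P_s < 1, so re-estimate on a finer time unit.
    """
    hours = window.duration_hours
    ev = events
    mask = (
        (ev["species"] == species)
        & ev["within_tagging_distance"].astype(bool)
        & (pd.to_datetime(ev["timestamp"]) >= window.start)
        & (pd.to_datetime(ev["timestamp"]) <= window.end)
    )
    if "site" in ev.columns:
        mask &= ev["site"] == window.site
    count = int(mask.sum())
    ps = count / hours
    if ps >= 1.0:
        raise ValueError(
            f"estimated P_s = {ps:.3g} >= 1.0; re-estimate with a finer "
            "time unit (e.g. minutes rather than hours) so P_s < 1"
        )
    if count == 0:
        warnings.warn(
            f"no within-tagging-distance events for {species!r}; "
            "P_s = 0 and P_Tag will be identically 0",
            stacklevel=2,
        )
    return ps


def p_tag(p_s: float, t: float) -> float:
    """Cumulative probability of ≥1 tagging opportunity: 1 − (1 − P_s)^t."""
    if not 0 <= p_s < 1:
        raise ValueError("p_s must be in [0, 1)")
    if t < 0:
        raise ValueError("t must be >= 0")
    return 1.0 - (1.0 - p_s) ** t


def probability_curve(p_s: float, max_hours: int, step: float = 1.0) -> TagProbabilityCurve:
    """Evaluate the cumulative curve on a regular grid of deployment hours."""
    times = np.arange(0.0, max_hours + step / 2, step)
    values = 1.0 - (1.0 - p_s) ** times
    if not 0 < p_s < 1:
        raise ValueError("p_s must be in (0, 1) for a curve")
    return TagProbabilityCurve(p_s=p_s, times=times, p_tag=values)


def time_to_probability(p_s: float, target: float) -> HoursToTarget:
    """Deployment hours needed to reach a target cumulative probability.

    Inverts the geometric curve: t = ln(1 − target) / ln(1 − P_s).  Returns
    the real-valued hours and the nearest-hour display value (half away
    from zero).
    """
    if not 0 < p_s < 1:
        raise ValueError("p_s must be strictly inside (0, 1)")
    if not 0 < target < 1:
        raise ValueError("target must be strictly inside (0, 1)")
    hours = math.log1p(-target) / math.log1p(-p_s)
    return HoursToTarget(hours=hours, hours_rounded=int(round_half_away(hours)))


def rate_ratio_test(
    count_a: int,
    hours_a: float,
    count_b: int,
    hours_b: float,
    alternative: str = "two-sided",
) -> RateRatioResult:
    """Two-sample Poisson rate comparison (conditional binomial exact test).

    Conditional on the total count k = count_a + count_b, count_a is
    Binomial(k, hours_a/(hours_a+hours_b)) under equal rates; the exact
    two-sided p-value comes from that binomial, with a normal-approximation
    Z reported alongside.  The confidence interval on the rate ratio is the
    exact (Clopper–Pearson) binomial proportion interval mapped through
    the odds transform.
    """
    if hours_a <= 0 or hours_b <= 0:
        raise ValueError("exposure hours must be > 0")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    k = count_a + count_b
    if k == 0:
        raise ValueError("rate ratio undefined: both counts are 0")

    p0 = hours_a / (hours_a + hours_b)
    test = stats.binomtest(count_a, k, p0, alternative=alternative)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")

    def _odds_to_ratio(pi: float) -> float:
        if pi >= 1.0:
            return math.inf
        return (pi / (1.0 - pi)) * (hours_b / hours_a)

    rate_a = count_a / hours_a
    rate_b = count_b / hours_b
    ratio = math.inf if rate_b == 0 else rate_a / rate_b
    z = (count_a - k * p0) / math.sqrt(k * p0 * (1.0 - p0))
    return RateRatioResult(
        rate_a=rate_a,
        rate_b=rate_b,
        rate_ratio=ratio,
        ci_low=_odds_to_ratio(ci.low),
        ci_high=_odds_to_ratio(ci.high),
        p_value=float(test.pvalue),
        z=float(z),
    )
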