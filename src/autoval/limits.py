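"""Derivation of autovalidation ranges and delta limits from data.

Laboratories set autovalidation ranges from one of several sources:
reference intervals (optionally widened by total allowable error),
critical limits, clinically significant cutoffs, professional consensus,
literature, or percentiles of the laboratory's own released results —
the latter reflecting the local patient population most directly.
Delta limits can likewise be taken as percentiles of observed
same-patient differences within a look-back window.

All derivations here are advisory: they produce LimitProposal artifacts
that must be explicitly reviewed and written into the engine
configuration — limits enter routine use only after documented approval.

Percentile definition: linear interpolation between order statistics.
For n sorted values x_1..x_n and level p in [0, 100], let
h = (n - 1) * p/100; the percentile is
x_{floor(h)+1} + (h - floor(h)) * (x_{floor(h)+2} - x_{floor(h)+1}),
i.e. numpy's "linear" method.  Fixed so that derived limits are
bit-reproducible across runs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import Interval

__all__ = [
    "LimitMethod",
    "LimitProposal",
    "percentile_limits",
    "delta_percentile_limits",
    "midpoint_limits",
    "reference_interval_with_tea",
    "propose_limits",
    "MIN_N",
]

#: Minimum number of historical values for a data-derived limit.
MIN_N = 20


class LimitMethod(str, enum.Enum):
    percentile = "percentile"
    reference_interval = "reference_interval"
    reference_interval_tea = "reference_interval_tea"
    midpoint = "midpoint"
    critical = "critical"
    clinical_cutoff = "clinical_cutoff"
    consensus = "consensus"
    literature = "literature"


@dataclass(frozen=True)
class LimitProposal:
    """An advisory limit proposal; never applied automatically."""

    test_code: str
    method: LimitMethod
    interval: Interval
    n_used: int = 0
    parameters: dict = field(default_factory=dict)


def _clean(values: Sequence[float], minimum: int) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and not np.isfinite(arr).all():
        bad = int((~np.isfinite(arr)).sum())
        raise ValueError(f"{bad} non-finite value(s) in input")
    if arr.size < minimum:
        raise ValueError(f"insufficient data: {arr.size} values, need >= {minimum}")
    return arr


def percentile_limits(
    values: Sequence[float], p_low: float = 5.0, p_high: float = 95.0
) -> Interval:
    """Empirical percentile interval of released results (default 5th-95th)."""
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    arr = _clean(values, MIN_N)
    low, high = np.percentile(arr, [p_low, p_high], method="linear")
    return Interval(low=float(low), high=float(high))


def delta_percentile_limits(
    paired_differences: Sequence[float], p_low: float = 5.0, p_high: float = 95.0
) -> Interval:
    """Percentile interval of observed same-patient paired differences.

    The caller computes the differences from same-patient result pairs
    within a stated window (e.g. 3 days); at least 20 pairs are required.
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValueError(f"need 0 <= p_low < p_high <= 100, got ({p_low}, {p_high})")
    arr = _clean(paired_differences, MIN_N)
    low, high = np.percentile(arr, [p_low, p_high], method="linear")
    return Interval(low=float(low), high=float(high))


def midpoint_limits(reference_interval: Interval, critical_limits: Interval) -> Interval:
    """Midpoints between the reference-interval median and each critical limit.

    low = (median_RI + critical_low)/2, high = (median_RI + critical_high)/2.
    One plausible reading of the midpoint approach; both intervals must be
    fully bounded.
    """
    for name, iv in (("reference_interval", reference_interval),
                     ("critical_limits", critical_limits)):
        if iv.low is None or iv.high is None:
            raise ValueError(f"{name} must be bounded on both sides")
    median_ri = (reference_interval.low + reference_interval.high) / 2.0
    return Interval(
        low=(median_ri + critical_limits.low) / 2.0,
        high=(median_ri + critical_limits.high) / 2.0,
    )


def reference_interval_with_tea(
    reference_interval: Interval, tea: float, tea_is_percent: bool
) -> Interval:
    """Reference interval widened by total allowable error (TEa).

    low - TEa and high + TEa, with TEa given either in test units
    (``tea_is_percent=False``) or as a percent of each limit
    (``tea_is_percent=True``).  The scale must be stated explicitly.
    """
    if reference_interval.low is None or reference_interval.high is None:
        raise ValueError("reference interval must be bounded on both sides")
    if tea < 0 or not math.isfinite(tea):
        raise ValueError("TEa must be finite and >= 0")
    if tea_is_percent:
        lo = reference_interval.low - abs(reference_interval.low) * tea / 100.0
        hi = reference_interval.high + abs(reference_interval.high) * tea / 100.0
    else:
        lo = reference_interval.low - tea
        hi = reference_interval.high + tea
    return Interval(low=lo, high=hi)


def propose_limits(
    test_code: str,
    method: LimitMethod | str,
    *,
    values: Optional[Sequence[float]] = None,
    interval: Optional[Interval] = None,
    reference_interval: Optional[Interval] = None,
    critical_limits: Optional[Interval] = None,
    p_low: float = 5.0,
    p_high: float = 95.0,
    tea: Optional[float] = None,
    tea_is_percent: bool = False,
) -> LimitProposal:
    """Build an advisory LimitProposal with the chosen method.

    Data-derived methods need ``values``; interval-echo methods
    (reference_interval, critical, clinical_cutoff, consensus, literature)
    need ``interval``; midpoint needs ``reference_interval`` and
    ``critical_limits``; reference_interval_tea needs
    ``reference_interval`` and ``tea``.
    """
    method = LimitMethod(method)
    if method is LimitMethod.percentile:
        if values is None:
            raise ValueError("percentile method requires values")
        iv = percentile_limits(values, p_low, p_high)
        return LimitProposal(test_code, method, iv, n_used=len(values),
                             parameters={"p_low": p_low, "p_high": p_high})
    if method is LimitMethod.midpoint:
        if reference_interval is None or critical_limits is None:
            raise ValueError("midpoint method requires reference_interval and critical_limits")
        iv = midpoint_limits(reference_interval, critical_limits)
        return LimitProposal(test_code, method, iv,
                             parameters={"reference_interval": reference_interval.model_dump(),
                                         "critical_limits": critical_limits.model_dump()})
    if method is LimitMethod.reference_interval_tea:
        if reference_interval is None or tea is None:
            raise ValueError("reference_interval_tea requires reference_interval and tea")
        iv = reference_interval_with_tea(reference_interval, tea, tea_is_percent)
        return LimitProposal(test_code, method, iv,
                             parameters={"tea": tea, "tea_is_percent": tea_is_percent})
    if method in (LimitMethod.reference_interval, LimitMethod.critical,
                  LimitMethod.clinical_cutoff, LimitMethod.consensus,
                  LimitMethod.literature):
        if interval is None:
            raise ValueError(f"{method.value} method requires an interval")
        return LimitProposal(test_code, method, interval)
    raise ValueError(f"unknown method {method!r}")  # pragma: no cover
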