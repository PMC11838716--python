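"""Delta check: consecutive-result comparison mathematics and rule.

A delta check compares a patient's current result with their most recent
prior result for the same test and holds the result for manual review when
the difference exceeds a limit.  Four difference calculations are
supported: absolute (units), percent (relative to the *prior* value), rate
(units per hour), and percent against a reference change value (RCV)
derived from analytical and within-subject biological variation.

The module also provides the index of individuality (II = CVi/CVg) and
the candidate-selection rule: delta checks are most informative for
measurands with II below 0.6, where an individual's results occupy a
narrow band relative to the population.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import (
    BiologicalVariation,
    DeltaConfig,
    DeltaMode,
    ResultRecord,
    TestDefinition,
)
from .outcomes import RuleId, RuleOutcome, Status

__all__ = [
    "DeltaResult",
    "delta_absolute",
    "delta_percent",
    "delta_rate",
    "reference_change_value",
    "individuality_index",
    "select_delta_candidates",
    "evaluate_delta",
    "load_biological_variation",
    "DEFAULT_II_THRESHOLD",
]

#: Candidate-selection cutoff on the index of individuality.
DEFAULT_II_THRESHOLD = 0.6


@dataclass(frozen=True)
class DeltaResult:
    """Outcome of one consecutive-result comparison."""

    mode: DeltaMode
    value: float  # computed difference, units depend on mode
    limit: float  # limit it was compared against (same units)
    prior_value: float
    prior_time: dt.datetime
    interval_hours: float
    exceeded: bool  # strictly |value| > limit; equality passes


def delta_absolute(current: float, prior: float) -> float:
    """Absolute difference current - prior, in test units."""
    return current - prior


def delta_percent(current: float, prior: float) -> float:
    """Percent difference 100*(current - prior)/prior.

    The denominator is the prior value: the change is expressed relative
    to the patient's previous state.  Note the asymmetry: a +100% change
    undone is a -50% change.
    """
    if prior == 0:
        raise ZeroDivisionError("percent delta undefined for prior value 0")
    return 100.0 * (current - prior) / prior


def delta_rate(current: float, prior: float, interval_hours: float) -> float:
    """Rate of change (current - prior)/interval, in units per hour."""
    if interval_hours <= 0:
        raise ValueError(
            f"interval_hours must be positive, got {interval_hours} "
            "(duplicate or misordered timestamps?)"
        )
    return (current - prior) / interval_hours


def reference_change_value(cv_analytical: float, cvi: float, z: float = 1.96) -> float:
    """Classical reference change value, in percent.

    RCV = sqrt(2) * z * sqrt(CVa^2 + CVi^2), the smallest difference
    between two serial results that exceeds combined analytical (CVa) and
    within-subject biological (CVi) variation at confidence z (two-sided
    1.96 for 95%).
    """
    if cv_analytical < 0 or cvi < 0:
        raise ValueError("CVs must be non-negative")
    if z <= 0:
        raise ValueError("z must be positive")
    return math.sqrt(2.0) * z * math.hypot(cv_analytical, cvi)


def individuality_index(biovar: BiologicalVariation) -> float:
    """Index of individuality II = CVi / CVg (dimensionless)."""
    if biovar.cvg == 0:
        raise ZeroDivisionError("II undefined for CVg = 0")
    return biovar.cvi / biovar.cvg


def select_delta_candidates(
    table: Iterable[tuple[str, BiologicalVariation]],
    threshold: float = DEFAULT_II_THRESHOLD,
) -> list[tuple[str, float]]:
    """Tests whose index of individuality is strictly below `threshold`.

    Returns (test, II) pairs sorted ascending by II — the best delta-check
    candidates first.
    """
    out = [
        (name, individuality_index(bv))
        for name, bv in table
    ]
    return sorted(
        ((name, ii) for name, ii in out if ii < threshold),
        key=lambda p: (p[1], p[0]),
    )


def load_biological_variation(path=None) -> list[tuple[str, BiologicalVariation]]:
    """Load a (measurand, CVi%, CVg%) table; defaults to the packaged fixture.

    The packaged table covers 21 common chemistry, coagulation and
    hematology measurands.
    """
    if path is None:
        src = resources.files("autoval.data").joinpath("biological_variation.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"measurand", "cvi", "cvg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biological-variation table missing columns: {sorted(missing)}")
    return [
        (str(row.measurand), BiologicalVariation(cvi=float(row.cvi), cvg=float(row.cvg)))
        for row in df.itertuples(index=False)
    ]


def _select_prior(
    record: ResultRecord,
    history: Sequence[ResultRecord],
    window_days: float,
) -> Optional[ResultRecord]:
    """Most recent same-patient, same-test prior within the look-back window."""
    cutoff = record.timestamp - dt.timedelta(days=window_days)
    eligible = [
        h
        for h in history
        if h.test_code == record.test_code
        and h.patient.patient_id == record.patient.patient_id
        and h.timestamp < record.timestamp
        and h.timestamp >= cutoff
        and h.value is not None
    ]
    if not eligible:
        return None
    return max(eligible, key=lambda h: h.timestamp)


def evaluate_delta(
    record: ResultRecord,
    history: Sequence[ResultRecord],
    cfg: DeltaConfig,
    testdef: TestDefinition,
) -> tuple[RuleOutcome, Optional[DeltaResult]]:
    """Delta rule: HOLD iff the configured difference strictly exceeds the limit.

    SKIPs (treated as pass for the conjunction) when no eligible prior
    exists within the look-back window — a result out of the delta time
    interval is autovalidated when all other criteria are met.  Equality
    with the limit passes; the HOLD reason identifies the direction.
    """
    if record.value is None:
        return (
            RuleOutcome(RuleId.delta, Status.HOLD, "missing_result", "no value to compare"),
            None,
        )
    prior = _select_prior(record, history, cfg.window_days)
    if prior is None:
        return (
            RuleOutcome(
                RuleId.delta,
                Status.SKIP,
                "no_prior_in_window",
                f"no prior result within {cfg.window_days} days",
            ),
            None,
        )
    interval_hours = (record.timestamp - prior.timestamp).total_seconds() / 3600.0

    limit = cfg.limit
    try:
        if cfg.mode is DeltaMode.absolute:
            value = delta_absolute(record.value, prior.value)
        elif cfg.mode is DeltaMode.percent:
            value = delta_percent(record.value, prior.value)
        elif cfg.mode is DeltaMode.rate:
            value = delta_rate(record.value, prior.value, interval_hours)
        elif cfg.mode is DeltaMode.rcv:
            assert testdef.biovar is not None  # enforced by config validation
            limit = reference_change_value(
                cfg.cv_analytical, testdef.biovar.cvi, cfg.z_value
            )
            value = delta_percent(record.value, prior.value)
        else:  # pragma: no cover - enum is exhaustive
            raise AssertionError(cfg.mode)
    except ZeroDivisionError:
        return (
            RuleOutcome(
                RuleId.delta,
                Status.HOLD,
                "delta_undefined",
                f"prior value 0 at {prior.timestamp.isoformat()}: percent change undefined",
            ),
            None,
        )
    except ValueError as e:
        return (
            RuleOutcome(RuleId.delta, Status.HOLD, "delta_undefined", str(e)),
            None,
        )

    exceeded = abs(value) > limit
    result = DeltaResult(
        mode=cfg.mode,
        value=value,
        limit=limit,
        prior_value=prior.value,
        prior_time=prior.timestamp,
        interval_hours=interval_hours,
        exceeded=exceeded,
    )
    if exceeded:
        direction = "increase" if value > 0 else "decrease"
        outcome = RuleOutcome(
            RuleId.delta,
            Status.HOLD,
            f"delta_{direction}_exceeded",
            f"{cfg.mode.value} delta {value:.4g} exceeds limit {limit:.4g} "
            f"(prior {prior.value:.4g} at {prior.timestamp.isoformat()})",
        )
    else:
        outcome = RuleOutcome(
            RuleId.delta,
            Status.PASS,
            "",
            f"{cfg.mode.value} delta {value:.4g} within limit {limit:.4g}",
        )
    return outcome, result
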