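"""The autovalidation rule engine.

Each result is evaluated against every configured rule — demographics,
analyzer flags, HIL interference indices, critical limits, autovalidation
range, delta check, cross-test consistency, and internal-QC gating — and
the decision is the conjunction: a result is autovalidated if and only if
no rule holds it.  All rules are equivalent and all are evaluated (no
short-circuit), so a held result reports every violated rule, which is
what a reviewer investigating discordances needs.

Boundary conventions, fixed so that verification can probe the decision
points: PASS is inclusive at autovalidation-range, HIL and consistency
limits; HOLD is inclusive at critical limits (a result *at* a critical
limit is critical).  Critical limits dominate the autovalidation range:
a critical result is held even if it lies inside the range.

A kill switch in the configuration unconditionally holds every result —
the mechanism to stop real-time release at any moment.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

from .config import (
    EngineConfig,
    QCPolicy,
    ResultRecord,
    Sex,
    TestDefinition,
    age_at,
)
from .delta import evaluate_delta
from .outcomes import Decision, RuleId, RuleOutcome, Status, ValidationDecision

__all__ = [
    "evaluate_demographics",
    "evaluate_flags",
    "evaluate_hil",
    "evaluate_critical",
    "evaluate_av_range",
    "evaluate_consistency",
    "evaluate_qc",
    "validate_record",
    "validate_batch",
    "BatchSummary",
    "DEFAULT_RULESET",
    "ReleaseChannel",
    "register_extension_rule",
    "clear_extension_rules",
    "UnknownTestError",
]


class UnknownTestError(KeyError):
    """The record's test_code has no TestDefinition in the configuration."""


def evaluate_demographics(record: ResultRecord, testdef: TestDefinition) -> RuleOutcome:
    """HOLD without usable age and sex, or when the age group is excluded."""
    p = record.patient
    if p.sex is Sex.unknown:
        return RuleOutcome(RuleId.demographics, Status.HOLD, "missing_sex",
                           "patient sex missing or unknown")
    if p.date_of_birth is None:
        return RuleOutcome(RuleId.demographics, Status.HOLD, "missing_age",
                           "patient date of birth missing")
    try:
        age = age_at(p, record.timestamp)
    except ValueError:
        return RuleOutcome(RuleId.demographics, Status.HOLD, "age_absurd",
                           "date of birth after result timestamp")
    if not testdef.age_included(age):
        return RuleOutcome(
            RuleId.demographics, Status.HOLD, "age_excluded",
            f"age {age:.2f} y outside included groups {testdef.age_groups_included}",
        )
    return RuleOutcome(RuleId.demographics, Status.PASS, "", f"age {age:.2f} y, sex {p.sex.value}")


def evaluate_flags(record: ResultRecord, testdef: TestDefinition) -> RuleOutcome:
    """HOLD on any analyzer flag configured as result-affecting.

    Flags not in the blocking set are informational: they do not block but
    are echoed in the detail so they appear in the audit log.  Results
    from analyzers excluded from autovalidation are held here too.
    """
    if testdef.analyzers_included and record.analyzer is not None \
            and record.analyzer not in testdef.analyzers_included:
        return RuleOutcome(
            RuleId.flags, Status.HOLD, "analyzer_excluded",
            f"analyzer {record.analyzer!r} not included for {testdef.test_code}",
        )
    blocking = sorted(set(record.flags) & testdef.flags_blocking)
    if blocking:
        return RuleOutcome(RuleId.flags, Status.HOLD, "blocking_flag",
                           "blocking flag(s): " + ", ".join(blocking))
    info = sorted(set(record.flags) - testdef.flags_blocking)
    detail = "informational flag(s): " + ", ".join(info) if info else "no flags"
    return RuleOutcome(RuleId.flags, Status.PASS, "", detail)


def evaluate_hil(record: ResultRecord, testdef: TestDefinition) -> RuleOutcome:
    """Interference gating on hemolysis / icterus / lipemia indices.

    HOLD when any configured index strictly exceeds its threshold (the
    threshold itself passes), or when a configured index was not measured.
    SKIP when the test has no HIL thresholds at all.
    """
    if not testdef.hil_thresholds:
        return RuleOutcome(RuleId.hil, Status.SKIP, "not_configured",
                           "no HIL thresholds configured")
    offending, missing = [], []
    for name, threshold in sorted(testdef.hil_thresholds.items()):
        measured = getattr(record.hil, name)
        if measured is None:
            missing.append(name)
        elif measured > threshold:
            offending.append((name, measured, threshold))
    if offending:
        name, measured, threshold = offending[0]
        return RuleOutcome(
            RuleId.hil, Status.HOLD, f"{name}_exceeded",
            "; ".join(f"{n} index {m:g} > limit {t:g}" for n, m, t in offending),
        )
    if missing:
        return RuleOutcome(RuleId.hil, Status.HOLD, "hil_missing",
                           "index not measured: " + ", ".join(missing))
    return RuleOutcome(RuleId.hil, Status.PASS, "", "all HIL indices within limits")


def evaluate_critical(record: ResultRecord, testdef: TestDefinition) -> RuleOutcome:
    """HOLD (with critical alert) at or beyond a critical limit.

    Critical results are never autovalidated; they go to immediate manual
    validation and clinician notification.  SKIPs when the value is
    missing (the range rule holds missing results).
    """
    if record.value is None:
        return RuleOutcome(RuleId.critical, Status.SKIP, "missing_result",
                           "no value to compare")
    lim = testdef.critical_limits
    if lim.low is None and lim.high is None:
        return RuleOutcome(RuleId.critical, Status.SKIP, "not_configured",
                           "no critical limits configured")
    if lim.low is not None and record.value <= lim.low:
        return RuleOutcome(RuleId.critical, Status.HOLD, "critical_low",
                           f"value {record.value:g} <= critical low {lim.low:g}")
    if lim.high is not None and record.value >= lim.high:
        return RuleOutcome(RuleId.critical, Status.HOLD, "critical_high",
                           f"value {record.value:g} >= critical high {lim.high:g}")
    return RuleOutcome(RuleId.critical, Status.PASS, "", "within critical limits")


def evaluate_av_range(record: ResultRecord, testdef: TestDefinition) -> RuleOutcome:
    """HOLD outside the autovalidation range (boundaries pass) or on a missing value."""
    if record.value is None:
        return RuleOutcome(RuleId.av_range, Status.HOLD, "missing_result",
                           "missing result for the test")
    rng = testdef.av_range
    if rng.low is not None and record.value < rng.low:
        return RuleOutcome(RuleId.av_range, Status.HOLD, "below_av_range",
                           f"value {record.value:g} < AV low {rng.low:g}")
    if rng.high is not None and record.value > rng.high:
        return RuleOutcome(RuleId.av_range, Status.HOLD, "above_av_range",
                           f"value {record.value:g} > AV high {rng.high:g}")
    return RuleOutcome(RuleId.av_range, Status.PASS, "", "within AV range")


def evaluate_consistency(
    sample_results: Sequence[ResultRecord],
    rules: Sequence,
) -> dict[str, list[RuleOutcome]]:
    """Per-sample plausibility checks on ratios of related tests.

    For each rule with both tests present on the sample: PASS when the
    ratio lies within the band (inclusive), HOLD otherwise; a violation
    marks BOTH participating results, since the error could be in either
    measurement.  SKIP when either test is absent.  A zero denominator
    holds both results with reason ``ratio_undefined``.

    Returns outcomes keyed by test_code (one entry per rule touching it).
    """
    by_test: dict[str, ResultRecord] = {}
    for r in sample_results:
        by_test.setdefault(r.test_code, r)
    out: dict[str, list[RuleOutcome]] = {}

    def add(code: str, outcome: RuleOutcome) -> None:
        out.setdefault(code, []).append(outcome)

    for rule in rules:
        num = by_test.get(rule.numerator_test)
        den = by_test.get(rule.denominator_test)
        pair = (rule.numerator_test, rule.denominator_test)
        if num is None or den is None or num.value is None or den.value is None:
            skip = RuleOutcome(RuleId.consistency, Status.SKIP, "test_absent",
                               f"{rule.rule_id}: pair incomplete on sample")
            for code in pair:
                if code in by_test:
                    add(code, skip)
            continue
        if den.value == 0:
            hold = RuleOutcome(RuleId.consistency, Status.HOLD, "ratio_undefined",
                               f"{rule.rule_id}: denominator {rule.denominator_test} is 0")
            for code in pair:
                add(code, hold)
            continue
        ratio = num.value / den.value
        if rule.limits.contains(ratio):
            ok = RuleOutcome(RuleId.consistency, Status.PASS, "",
                             f"{rule.rule_id}: ratio {ratio:.4g} within limits")
            for code in pair:
                add(code, ok)
        else:
            hold = RuleOutcome(
                RuleId.consistency, Status.HOLD, "ratio_outside_limits",
                f"{rule.rule_id}: ratio {ratio:.4g} outside "
                f"[{rule.limits.low}, {rule.limits.high}]",
            )
            for code in pair:
                add(code, hold)
    return out


def evaluate_qc(
    testdef: TestDefinition,
    policy: Optional[QCPolicy],
    now: dt.datetime,
) -> RuleOutcome:
    """Internal-QC gating: failed or expired QC disables autovalidation."""
    if policy is None:
        return RuleOutcome(RuleId.qc, Status.SKIP, "not_configured",
                           "no QC policy for this test")
    if not policy.in_control:
        return RuleOutcome(RuleId.qc, Status.HOLD, "qc_failed",
                           "internal quality control criteria not met")
    age_h = (now - policy.last_pass_time).total_seconds() / 3600.0
    if age_h > policy.max_age_hours:
        return RuleOutcome(
            RuleId.qc, Status.HOLD, "qc_expired",
            f"last QC pass {age_h:.1f} h ago exceeds {policy.max_age_hours:g} h",
        )
    return RuleOutcome(RuleId.qc, Status.PASS, "", f"QC in control ({age_h:.1f} h ago)")


# Dispatch table for the per-record rules; verification's mutation harness
# swaps entries here to prove that each rule's boundary convention is live.
DEFAULT_RULESET: Mapping[str, Callable] = {
    "demographics": evaluate_demographics,
    "flags": evaluate_flags,
    "hil": evaluate_hil,
    "critical": evaluate_critical,
    "av_range": evaluate_av_range,
}

# Named extension point for additional rules (repeat testing, reflex
# testing, PBRTQC, clinical diagnosis ...). Each hook takes
# (record, testdef) and returns a RuleOutcome or None.
_EXTENSION_RULES: list[Callable[[ResultRecord, TestDefinition], Optional[RuleOutcome]]] = []


def register_extension_rule(hook) -> None:
    _EXTENSION_RULES.append(hook)


def clear_extension_rules() -> None:
    _EXTENSION_RULES.clear()


class ReleaseChannel:
    """Downstream release of autovalidated decisions (e.g. to the LIS).

    The engine itself never releases; callers attach a channel when they
    want autovalidated results emitted.  Verification runs must never
    attach one — see ``verification.SentinelChannel``.
    """

    def __init__(self) -> None:
        self.released: list[ValidationDecision] = []

    def release(self, decision: ValidationDecision) -> None:
        self.released.append(decision)


def validate_record(
    record: ResultRecord,
    config: EngineConfig,
    history: Sequence[ResultRecord] = (),
    sample_context: Sequence[ResultRecord] = (),
    now: Optional[dt.datetime] = None,
    ruleset: Optional[Mapping[str, Callable]] = None,
    release_channel: Optional[ReleaseChannel] = None,
) -> ValidationDecision:
    """Evaluate one result against every applicable rule.

    Rules run in a fixed order (kill switch, demographics, flags, HIL,
    critical, AV range, delta, consistency, QC) but all of them run, so
    every reason for holding is reported; the verdict is therefore
    invariant under rule order.  AUTOVALIDATED iff no rule HOLDs.
    """
    testdef = config.tests.get(record.test_code)
    if testdef is None:
        raise UnknownTestError(
            f"test_code {record.test_code!r} not defined in configuration"
        )
    rules = dict(DEFAULT_RULESET)
    if ruleset:
        rules.update(ruleset)
    now = now if now is not None else record.timestamp

    outcomes: list[RuleOutcome] = []
    if config.kill_switch:
        outcomes.append(RuleOutcome(RuleId.kill_switch, Status.HOLD, "kill_switch",
                                    "autovalidation stopped by kill switch"))
    for name in ("demographics", "flags", "hil", "critical", "av_range"):
        outcomes.append(rules[name](record, testdef))

    if testdef.delta is not None:
        delta_fn = rules.get("delta", evaluate_delta)
        outcome, _ = delta_fn(record, history, testdef.delta, testdef)
        outcomes.append(outcome)
    else:
        outcomes.append(RuleOutcome(RuleId.delta, Status.SKIP, "not_configured",
                                    "no delta configuration"))

    applicable = [
        r for r in config.consistency_rules
        if record.test_code in (r.numerator_test, r.denominator_test)
    ]
    if applicable:
        consistency_fn = rules.get("consistency", evaluate_consistency)
        sample = list(sample_context)
        if all(r is not record for r in sample):
            sample.append(record)
        outcomes.extend(consistency_fn(sample, applicable).get(record.test_code, []))

    outcomes.append(evaluate_qc(testdef, config.qc_policies.get(record.test_code), now))

    for hook in _EXTENSION_RULES:
        extra = hook(record, testdef)
        if extra is not None:
            outcomes.append(extra)

    any_hold = any(o.status is Status.HOLD for o in outcomes)
    critical_alert = any(
        o.rule is RuleId.critical and o.status is Status.HOLD for o in outcomes
    )
    decision = ValidationDecision(
        record=record,
        outcomes=tuple(outcomes),
        decision=Decision.HELD if any_hold else Decision.AUTOVALIDATED,
        decided_at=now,
        critical_alert=critical_alert,
    )
    if release_channel is not None and decision.decision is Decision.AUTOVALIDATED:
        release_channel.release(decision)
    return decision


@dataclass(frozen=True)
class BatchSummary:
    n: int
    n_autovalidated: int

    @property
    def percent_autovalidated(self) -> Optional[float]:
        if self.n == 0:
            return None
        return 100.0 * self.n_autovalidated / self.n


def validate_batch(
    records: Sequence[ResultRecord],
    config: EngineConfig,
    history: Sequence[ResultRecord] = (),
    now: Optional[dt.datetime] = None,
    release_channel: Optional[ReleaseChannel] = None,
) -> tuple[list[ValidationDecision], BatchSummary]:
    """Validate a result stream; earlier batch records serve as delta priors.

    The sample context for consistency checks is every record sharing the
    sample_id.  Returns per-record decisions plus the autovalidated count
    and percentage (absent for an empty batch).
    """
    by_sample: dict[str, list[ResultRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    # chronological so that intra-batch priors are visible to later records
    ordered = sorted(range(len(records)), key=lambda i: (records[i].timestamp, i))
    decisions_by_index: dict[int, ValidationDecision] = {}
    for i in ordered:
        r = records[i]
        intra = [
            records[j] for j in ordered
            if records[j].timestamp < r.timestamp
            and records[j].patient.patient_id == r.patient.patient_id
            and records[j].test_code == r.test_code
        ]
        decisions_by_index[i] = validate_record(
            r,
            config,
            history=list(history) + intra,
            sample_context=by_sample[r.sample_id],
            now=now,
            release_channel=release_channel,
        )
    decisions = [decisions_by_index[i] for i in range(len(records))]
    n_auto = sum(d.decision is Decision.AUTOVALIDATED for d in decisions)
    return decisions, BatchSummary(n=len(records), n_autovalidated=n_auto)
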