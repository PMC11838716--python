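"""Two-phase verification of a configured autovalidation algorithm.

Phase I (technical verification) auto-generates boundary and absurd test
cases for every rule enabled on a test — values above, below and at each
decision point, absurd demographics, missing results, blocking and
informational flags, delta-window scenarios and multi-rule challenges —
runs them through the engine with the release channel disabled, and
reports yes/no concordance per case.

Phase II compares automatic decisions with manual validation labels on a
real decision stream and reports the percentage autovalidated, the full
auto-by-manual concordance table, and the critical discordances: results
the engine autovalidated but a human rejected, which require review by
the autovalidation team.

A hard guarantee holds throughout: no result is released during
verification.  ``SentinelChannel`` raises (and counts) on any release
attempt, and every report records ``released_results`` which must be 0.

The expected yes/no label of each generated case is computed by an
independent plain-boolean restatement of the documented boundary
conventions, not by the engine itself, so Phase I genuinely cross-checks
the engine's conventions; single-rule mutations of the engine produce
discordances exactly at the affected decision points.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

from .config import (
    EngineConfig,
    HILIndices,
    PatientInfo,
    ResultRecord,
    Sex,
    TestDefinition,
    age_at,
)
from .delta import reference_change_value
from .engine import ReleaseChannel, validate_record
from .outcomes import Decision, ValidationDecision

__all__ = [
    "VerificationCase",
    "VerificationReport",
    "SentinelChannel",
    "VerificationReleaseError",
    "generate_phase1_cases",
    "run_phase1",
    "run_phase2",
    "export_table4",
]


class VerificationReleaseError(RuntimeError):
    """A result release was attempted during verification."""


class SentinelChannel(ReleaseChannel):
    """Release channel that must never fire; counts and raises if it does."""

    def __init__(self) -> None:
        super().__init__()
        self.attempts = 0

    def release(self, decision: ValidationDecision) -> None:
        self.attempts += 1
        raise VerificationReleaseError(
            f"attempted release of {decision.record.sample_id}/"
            f"{decision.record.test_code} during verification"
        )


@dataclass
class VerificationCase:
    """One simulated yes/no scenario for Phase I."""

    case_id: str
    rule_label: str  # spreadsheet row label, e.g. "Result at: low limit of AV range"
    description: str
    record: ResultRecord
    history: list[ResultRecord] = field(default_factory=list)
    sample_context: list[ResultRecord] = field(default_factory=list)
    qc_in_control: Optional[bool] = None  # override config QC state for this case
    expected: str = "YES"  # autovalidation expected?
    actual: Optional[str] = None
    concordant: Optional[bool] = None
    remark: str = ""


@dataclass
class VerificationReport:
    phase: str  # "I" or "II"
    n_cases: int
    n_concordant: int
    discordances: list[str] = field(default_factory=list)  # case/record ids + detail
    percent_autovalidated: Optional[float] = None
    concordance_table: dict[str, int] = field(default_factory=dict)
    critical_discordances: list[str] = field(default_factory=list)
    released_results: int = 0
    notes: list[str] = field(default_factory=list)
    target_percent: Optional[float] = None
    target_met: Optional[bool] = None

    @property
    def percent_concordant(self) -> Optional[float]:
        if self.n_cases == 0:
            return None
        return 100.0 * self.n_concordant / self.n_cases


# ---------------------------------------------------------------------------
# Phase I case generation


def _base_patient(when: dt.datetime, testdef: TestDefinition) -> PatientInfo:
    """An adult (or mid-included-age) patient that passes demographics."""
    lo, hi = testdef.age_groups_included[0]
    mid = min(max((lo + hi) / 2.0, lo + 0.5), 100.0)
    dob = when.date() - dt.timedelta(days=int(mid * 365.25) + 1)
    return PatientInfo(patient_id="VERIF-PT", date_of_birth=dob, sex=Sex.female)


def _mid_value(testdef: TestDefinition) -> float:
    rng = testdef.av_range
    if rng.low is not None and rng.high is not None:
        return (rng.low + rng.high) / 2.0
    if rng.low is not None:
        return rng.low + 1.0
    if rng.high is not None:
        return rng.high - 1.0
    return 1.0


def _epsilon(testdef: TestDefinition) -> float:
    """One unit in the last reported decimal place."""
    return 10.0 ** (-testdef.precision)


def _delta_limit(testdef: TestDefinition) -> Optional[float]:
    cfg = testdef.delta
    if cfg is None:
        return None
    if cfg.mode.value == "rcv":
        return reference_change_value(cfg.cv_analytical, testdef.biovar.cvi, cfg.z_value)
    return cfg.limit


def expected_autovalidation(case: VerificationCase, testdef: TestDefinition,
                            config: EngineConfig) -> bool:
    """Independent restatement of the documented conventions.

    Plain boolean logic, deliberately written without reference to the
    engine's rule functions: inclusive PASS at AV/HIL/consistency limits,
    inclusive HOLD at critical limits, strict exceedance for delta,
    conjunction over all rules.
    """
    r = case.record
    p = r.patient
    if config.kill_switch:
        return False
    # demographics
    if p.sex is Sex.unknown or p.date_of_birth is None:
        return False
    if p.date_of_birth > r.timestamp.date():
        return False
    age = age_at(p, r.timestamp)
    if not any(lo <= age < hi for lo, hi in testdef.age_groups_included):
        return False
    # flags
    if set(r.flags) & testdef.flags_blocking:
        return False
    # HIL
    for name, threshold in testdef.hil_thresholds.items():
        measured = getattr(r.hil, name)
        if measured is None or measured > threshold:
            return False
    # value-based rules
    if r.value is None:
        return False
    cl = testdef.critical_limits
    if cl.low is not None and r.value <= cl.low:
        return False
    if cl.high is not None and r.value >= cl.high:
        return False
    av = testdef.av_range
    if av.low is not None and r.value < av.low:
        return False
    if av.high is not None and r.value > av.high:
        return False
    # delta: most recent prior within window, strict exceedance holds
    if testdef.delta is not None:
        cfg = testdef.delta
        cutoff = r.timestamp - dt.timedelta(days=cfg.window_days)
        priors = [
            h for h in case.history
            if h.test_code == r.test_code
            and h.patient.patient_id == p.patient_id
            and cutoff <= h.timestamp < r.timestamp
            and h.value is not None
        ]
        if priors:
            prior = max(priors, key=lambda h: h.timestamp)
            hours = (r.timestamp - prior.timestamp).total_seconds() / 3600.0
            if cfg.mode.value == "absolute":
                diff, lim = r.value - prior.value, cfg.limit
            elif cfg.mode.value == "rate":
                diff, lim = (r.value - prior.value) / hours, cfg.limit
            else:  # percent / rcv
                if prior.value == 0:
                    return False
                diff = 100.0 * (r.value - prior.value) / prior.value
                lim = _delta_limit(testdef)
            if abs(diff) > lim:
                return False
    # consistency (inclusive band; zero denominator holds)
    by_test = {c.test_code: c for c in case.sample_context} | {r.test_code: r}
    for rule in config.consistency_rules:
        if r.test_code not in (rule.numerator_test, rule.denominator_test):
            continue
        num = by_test.get(rule.numerator_test)
        den = by_test.get(rule.denominator_test)
        if num is None or den is None or num.value is None or den.value is None:
            continue
        if den.value == 0:
            return False
        ratio = num.value / den.value
        if rule.limits.low is not None and ratio < rule.limits.low:
            return False
        if rule.limits.high is not None and ratio > rule.limits.high:
            return False
    # QC
    policy = config.qc_policies.get(r.test_code)
    in_control = case.qc_in_control if case.qc_in_control is not None \
        else (policy.in_control if policy else None)
    if policy is not None and in_control is False:
        return False
    if policy is not None and in_control:
        age_h = (r.timestamp - policy.last_pass_time).total_seconds() / 3600.0
        if age_h > policy.max_age_hours:
            return False
    return True


def generate_phase1_cases(
    testdef: TestDefinition, config: EngineConfig
) -> list[VerificationCase]:
    """Boundary/absurd case set for one test, with expected yes/no labels.

    For each bounded decision point (AV low/high, each HIL threshold,
    each critical limit, the delta limit) a case is emitted at, just
    below and just above the point, with epsilon = one unit in the last
    reported decimal.  Unbounded limits are skipped with a note in the
    case list.  Expected labels come from the documented conventions via
    ``expected_autovalidation``, always as the full rule conjunction.
    """
    when = dt.datetime(2025, 6, 1, 9, 0)
    patient = _base_patient(when, testdef)
    eps = _epsilon(testdef)
    mid = _mid_value(testdef)
    cases: list[VerificationCase] = []
    counter = [0]
    sample_counter = [0]

    def rec(value: Optional[float] = None, **overrides) -> ResultRecord:
        sample_counter[0] += 1
        base = dict(
            sample_id=f"VERIF-S{sample_counter[0]:03d}",
            test_code=testdef.test_code, value=value,
            unit=testdef.unit, timestamp=when, patient=patient,
            hil=HILIndices(hemolysis=0.0, icterus=0.0, lipemia=0.0),
        )
        base.update(overrides)
        return ResultRecord(**base)

    def add(rule_label: str, description: str, record: ResultRecord,
            history: Optional[list[ResultRecord]] = None,
            sample_context: Optional[list[ResultRecord]] = None,
            qc_in_control: Optional[bool] = None) -> None:
        counter[0] += 1
        case = VerificationCase(
            case_id=f"{testdef.test_code}-{counter[0]:03d}",
            rule_label=rule_label, description=description,
            record=record, history=history or [],
            sample_context=sample_context or [],
            qc_in_control=qc_in_control,
        )
        case.expected = "YES" if expected_autovalidation(case, testdef, config) else "NO"
        cases.append(case)

    # demographics: nominal, absurd age, excluded groups, absurd sex
    add("Patient gender M or F", "nominal adult, mid-range value", rec(mid))
    add("Patient gender absurd value", "sex unknown",
        rec(mid, patient=patient.model_copy(update={"sex": Sex.unknown})))
    absurd_dob = when.date() - dt.timedelta(days=int(130 * 365.25))
    add("Patient age absurd value", "age 130 y",
        rec(mid, patient=patient.model_copy(update={"date_of_birth": absurd_dob})))
    add("Patient age absurd value", "date of birth missing",
        rec(mid, patient=patient.model_copy(update={"date_of_birth": None})))
    lo_age = min(lo for lo, _ in testdef.age_groups_included)
    if lo_age > 0:
        young_dob = when.date() - dt.timedelta(days=max(int(lo_age * 365.25 / 2), 10))
        add("Age group not included in the AV", "patient below included age groups",
            rec(mid, patient=patient.model_copy(update={"date_of_birth": young_dob})))
    add("Age group included in the AV", "patient inside included age group", rec(mid))

    # missing result
    add("Missing result for a test", "value absent", rec(None))

    # analyzer flags
    for flag in sorted(testdef.flags_blocking):
        add("Data alarms and/or flags affecting the result",
            f"blocking flag {flag}", rec(mid, flags=[flag]))
    add("Data alarms and/or flags not affecting the result",
        "informational flag INFO_ONLY", rec(mid, flags=["INFO_ONLY"]))

    # HIL thresholds: below / at / above each configured index limit
    for name, threshold in sorted(testdef.hil_thresholds.items()):
        for label, idx_val, where in (
            (f"Result within: {name} index limits", max(threshold - 1.0, 0.0), "below"),
            (f"Result within: {name} index limits", threshold, "at"),
            (f"Result outside: {name} index limits", threshold + 1.0, "above"),
        ):
            hil = HILIndices(hemolysis=0.0, icterus=0.0, lipemia=0.0).model_copy(
                update={name: idx_val})
            add(label, f"{name} index {where} limit ({idx_val:g})", rec(mid, hil=hil))

    # AV range boundaries: at / just below / just above each bounded limit
    av = testdef.av_range
    if av.low is not None:
        add("Result at: low limit of AV range", f"value {av.low:g}", rec(av.low))
        add("Result below AV range", f"value {av.low - eps:g}", rec(av.low - eps))
    if av.high is not None:
        add("Result at: high limit of AV range", f"value {av.high:g}", rec(av.high))
        add("Result above AV range", f"value {av.high + eps:g}", rec(av.high + eps))

    # critical limits: at the limit (critical, expected NO) and just inside
    cl = testdef.critical_limits
    if cl.low is not None:
        add("Result at critical low limit", f"value {cl.low:g}", rec(cl.low))
        add("Result just inside critical low limit", f"value {cl.low + eps:g}",
            rec(cl.low + eps))
    if cl.high is not None:
        add("Result at critical high limit", f"value {cl.high:g}", rec(cl.high))
        add("Result just inside critical high limit", f"value {cl.high - eps:g}",
            rec(cl.high - eps))

    # delta check: at / just above the limit, and prior outside the window
    if testdef.delta is not None:
        cfg = testdef.delta
        lim = _delta_limit(testdef)
        prior_when = when - dt.timedelta(hours=min(24.0, cfg.window_days * 12.0))
        prior = rec(mid, timestamp=prior_when)
        hours = (when - prior_when).total_seconds() / 3600.0
        if cfg.mode.value == "absolute":
            at_val, above_val = mid + lim, mid + lim + eps
        elif cfg.mode.value == "rate":
            at_val, above_val = mid + lim * hours, mid + lim * hours + eps
        else:  # percent / rcv
            at_val, above_val = mid * (1 + lim / 100.0), mid * (1 + lim / 100.0) + eps
        add("Result within: delta check limits", "delta exactly at limit",
            rec(at_val), history=[prior])
        add("Result outside: delta check limits", "delta just above limit",
            rec(above_val), history=[prior])
        stale_when = when - dt.timedelta(days=cfg.window_days + 1)
        stale = rec(mid * 3, timestamp=stale_when)
        add("Result out of delta check time interval (all other criteria met)",
            "large change but prior older than window", rec(mid), history=[stale])

    # consistency rules touching this test
    for rule in config.consistency_rules:
        if testdef.test_code not in (rule.numerator_test, rule.denominator_test):
            continue
        i_am_numerator = testdef.test_code == rule.numerator_test
        other_code = rule.denominator_test if i_am_numerator else rule.numerator_test
        other_def = config.tests[other_code]
        band = rule.limits
        in_ratio = ((band.low + band.high) / 2.0
                    if band.low is not None and band.high is not None
                    else (band.high if band.high is not None else band.low))
        out_ratio = (band.high * 2.0 if band.high is not None else band.low / 2.0)
        for label, ratio in (
            ("Result included in additional rule within limits (consistency check)",
             in_ratio),
            ("Result included in additional rule outside limits (consistency check)",
             out_ratio),
        ):
            # the case record keeps its own mid-range value so that only
            # the consistency verdict distinguishes YES from NO
            mine = mid
            other = mine / ratio if i_am_numerator else mine * ratio
            me = rec(mine)
            partner = ResultRecord(
                sample_id=me.sample_id, test_code=other_code, value=other,
                unit=other_def.unit, timestamp=when, patient=patient,
                hil=HILIndices(hemolysis=0.0, icterus=0.0, lipemia=0.0),
            )
            add(label, f"{rule.rule_id} ratio {ratio:g}", me,
                sample_context=[me, partner])

    # QC gating
    if testdef.test_code in config.qc_policies:
        add("IQC within criteria", "QC in control", rec(mid), qc_in_control=True)
        add("IQC criteria not met", "QC out of control", rec(mid), qc_in_control=False)

    # combined multi-rule challenge
    bad_flags = sorted(testdef.flags_blocking)[:1]
    worst = rec(
        (av.high + eps * 10) if av.high is not None else mid,
        flags=bad_flags,
        patient=patient.model_copy(update={"sex": Sex.unknown}),
    )
    add("Multiple rule challenges", "absurd sex + blocking flag + above AV range", worst)

    unbounded = [side for side, v in (("AV low", av.low), ("AV high", av.high),
                                      ("critical low", cl.low), ("critical high", cl.high))
                 if v is None]
    if unbounded:
        cases[-1].remark += f" (unbounded limits skipped: {', '.join(unbounded)})"
    return cases


def run_phase1(
    cases: Sequence[VerificationCase],
    config: EngineConfig,
    ruleset: Optional[Mapping[str, Callable]] = None,
) -> VerificationReport:
    """Execute Phase I cases through the engine; no result is released.

    ``ruleset`` overrides individual rule functions — the mutation-testing
    hook used to prove each boundary convention is live.
    """
    sentinel = SentinelChannel()
    n_conc = 0
    discordances: list[str] = []
    for case in cases:
        cfg = config
        if case.qc_in_control is not None and case.record.test_code in config.qc_policies:
            policy = config.qc_policies[case.record.test_code].model_copy(
                update={"in_control": case.qc_in_control})
            cfg = config.model_copy(
                update={"qc_policies": {**config.qc_policies,
                                        case.record.test_code: policy}})
        decision = validate_record(
            case.record, cfg,
            history=case.history,
            sample_context=case.sample_context,
            now=case.record.timestamp,
            ruleset=ruleset,
            release_channel=None,  # verification: release disabled
        )
        case.actual = "YES" if decision.decision is Decision.AUTOVALIDATED else "NO"
        case.concordant = case.actual == case.expected
        if case.concordant:
            n_conc += 1
        else:
            holds = ", ".join(f"{o.rule.value}:{o.reason_code}" for o in decision.holds)
            discordances.append(
                f"{case.case_id} [{case.rule_label}] expected {case.expected} "
                f"got {case.actual}" + (f" (holds: {holds})" if holds else "")
            )
    return VerificationReport(
        phase="I",
        n_cases=len(cases),
        n_concordant=n_conc,
        discordances=discordances,
        released_results=sentinel.attempts,
    )


def run_phase2(
    decisions: Sequence[ValidationDecision],
    manual_labels: Mapping[str, str],
    target_percent: Optional[float] = None,
) -> VerificationReport:
    """Compare automatic decisions with manual validation labels.

    ``manual_labels`` maps "sample_id/test_code" to "accept" or "reject".
    Concordance pairs auto-AUTOVALIDATED with manual accept; results
    autovalidated but manually rejected are the critical discordances
    requiring team review; held-but-accepted ones are benign (reported
    only).  ``target_percent`` is the predefined autovalidation-rate
    target the laboratory set before verification.
    """
    ids = [f"{d.record.sample_id}/{d.record.test_code}" for d in decisions]
    missing = [i for i in ids if i not in manual_labels]
    if missing:
        raise ValueError("manual label missing for record(s): " + ", ".join(missing))
    bad = {i: manual_labels[i] for i in ids if manual_labels[i] not in ("accept", "reject")}
    if bad:
        raise ValueError(f"manual labels must be accept/reject, got {bad}")

    table = {"auto_yes/manual_accept": 0, "auto_yes/manual_reject": 0,
             "auto_no/manual_accept": 0, "auto_no/manual_reject": 0}
    critical: list[str] = []
    benign: list[str] = []
    n_auto = 0
    for d, rid in zip(decisions, ids):
        auto_yes = d.decision is Decision.AUTOVALIDATED
        n_auto += auto_yes
        accept = manual_labels[rid] == "accept"
        key = f"auto_{'yes' if auto_yes else 'no'}/manual_{'accept' if accept else 'reject'}"
        table[key] += 1
        if auto_yes and not accept:
            critical.append(rid)
        elif not auto_yes and accept:
            benign.append(rid)
    n = len(decisions)
    n_conc = table["auto_yes/manual_accept"] + table["auto_no/manual_reject"]
    pct = 100.0 * n_auto / n if n else None
    report = VerificationReport(
        phase="II",
        n_cases=n,
        n_concordant=n_conc,
        discordances=critical + benign,
        percent_autovalidated=pct,
        concordance_table=table,
        critical_discordances=critical,
        released_results=0,
        target_percent=target_percent,
        target_met=(None if target_percent is None or pct is None
                    else pct >= target_percent),
    )
    if benign:
        report.notes.append(
            f"{len(benign)} held-but-manually-accepted result(s) (benign discordance)"
        )
    return report


# ---------------------------------------------------------------------------
# Spreadsheet export

_EXPECTED_ORDER_B = ["YES", "NO"]


def export_table4(
    cases: Sequence[VerificationCase],
    config: EngineConfig,
    path: str | Path,
    which: str = "B",
    test_code: Optional[str] = None,
) -> Path:
    """Write the technical-verification spreadsheet as CSV.

    Layout "A" is the cross-test sheet (absurd demographics, missing
    results, instrument errors, across all tests); layout "B" is the
    per-test sheet with rows for HIL limits, AV range, delta limits and
    age groups.  Header rows carry institution/department/instrument/LIS
    version/date/verifier from the configuration metadata.
    """
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    rows = list(cases)
    if which == "A":
        cross = ("Patient gender", "Patient age", "Missing result",
                 "Data alarms", "Multiple rule")
        rows = [c for c in rows if c.rule_label.startswith(cross)]
    elif test_code is not None:
        rows = [c for c in rows if c.record.test_code == test_code]
    md = config.metadata
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["Institution:", md.institution])
        w.writerow(["Department:", md.department])
        if which == "B":
            w.writerow(["Test name:", test_code or (rows[0].record.test_code if rows else "")])
            w.writerow(["Instrument:", md.instrument])
        w.writerow(["LIS version:", md.lis_version])
        w.writerow(["Date:", dt.date.today().isoformat(), "Verifier name:", md.verifier])
        w.writerow([])
        w.writerow(["AV rule", "Sample ID (Barcode)", "Result of AV (Yes/No)",
                    "Expected", "Remark"])
        for expected in _EXPECTED_ORDER_B:
            w.writerow([f"Result with expected {expected} outcome for AV"])
            for c in rows:
                if c.expected != expected:
                    continue
                w.writerow([
                    c.rule_label,
                    c.record.sample_id,
                    "" if c.actual is None else ("Yes" if c.actual == "YES" else "No"),
                    "Yes" if c.expected == "YES" else "No",
                    (c.description + (f"; {c.remark}" if c.remark else "")),
                ])
    return path
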