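"""Domain data model and rule-configuration loading.

Every rule evaluated by the engine is parameterized here: per-test
autovalidation ranges, critical limits, HIL interference thresholds,
delta-check configuration, demographic (age-group) inclusion, blocking
analyzer flags, cross-test consistency rules and internal-QC gating.

Configurations are declarative YAML (or JSON) documents with a
``schema_version`` field so that rule changes leave an auditable history.
All invariants are validated on load and every violation is reported with
the path to the offending field.
"""

from __future__ import annotations

import calendar
import datetime as dt
import enum
import math
from pathlib import Path
from typing import Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

__all__ = [
    "Sex",
    "PatientClass",
    "DeltaMode",
    "EngineMode",
    "PatientInfo",
    "HILIndices",
    "ResultRecord",
    "Interval",
    "DeltaConfig",
    "BiologicalVariation",
    "TestDefinition",
    "ConsistencyRule",
    "QCPolicy",
    "ReportMetadata",
    "EngineConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "age_at",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A configuration document failed to parse or validate."""


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class PatientClass(str, enum.Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"
    unknown = "unknown"


class DeltaMode(str, enum.Enum):
    absolute = "absolute"
    percent = "percent"
    rate = "rate"
    rcv = "rcv"


class EngineMode(str, enum.Enum):
    """Invocation style: batch command vs streaming callback.

    The decision logic is identical; only the trigger differs, so a
    laboratory can start with manually triggered runs and move to
    real-time release later without re-verifying the rule logic.
    """

    manual_trigger = "manual_trigger"
    real_time = "real_time"


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PatientInfo(_Model):
    patient_id: str = Field(min_length=1)
    date_of_birth: Optional[dt.date] = None
    sex: Sex = Sex.unknown
    location: Optional[str] = None
    patient_class: PatientClass = PatientClass.unknown


class HILIndices(_Model):
    """Semi-quantitative hemolysis / icterus / lipemia indices."""

    hemolysis: Optional[float] = Field(default=None, ge=0)
    icterus: Optional[float] = Field(default=None, ge=0)
    lipemia: Optional[float] = Field(default=None, ge=0)

    @field_validator("hemolysis", "icterus", "lipemia")
    @classmethod
    def _finite(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not math.isfinite(v):
            raise ValueError("HIL index must be finite")
        return v


class ResultRecord(_Model):
    """One analyzer result with its patient and sample context."""

    sample_id: str = Field(min_length=1)
    test_code: str = Field(min_length=1)
    value: Optional[float] = None
    unit: str = ""
    timestamp: dt.datetime
    patient: PatientInfo
    analyzer: Optional[str] = None
    flags: list[str] = Field(default_factory=list)
    hil: HILIndices = Field(default_factory=HILIndices)

    @field_validator("value")
    @classmethod
    def _finite_value(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not math.isfinite(v):
            raise ValueError("result value must be finite")
        return v

    @model_validator(mode="after")
    def _dob_not_future(self) -> "ResultRecord":
        dob = self.patient.date_of_birth
        if dob is not None and dob > self.timestamp.date():
            raise ValueError("date_of_birth is after the result timestamp")
        return self


class Interval(_Model):
    """A possibly half-unbounded numeric interval (None = unbounded)."""

    low: Optional[float] = None
    high: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "Interval":
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError(f"interval low ({self.low}) > high ({self.high})")
        return self

    def contains(self, x: float) -> bool:
        """Inclusive membership; unbounded sides always pass."""
        if self.low is not None and x < self.low:
            return False
        if self.high is not None and x > self.high:
            return False
        return True


class DeltaConfig(_Model):
    """Consecutive-result comparison settings for one test.

    ``limit`` is in test units (absolute), percent (percent), or units
    per hour (rate); for mode ``rcv`` the limit is computed from
    ``cv_analytical`` and the test's within-subject CV at confidence
    ``z_value`` and ``limit`` is ignored.
    """

    mode: DeltaMode
    limit: float = Field(default=1.0, gt=0)
    window_days: float = Field(gt=0)
    z_value: float = Field(default=1.96, gt=0)
    cv_analytical: float = Field(default=0.0, ge=0)


class BiologicalVariation(_Model):
    """Within-subject (CVi) and between-subject (CVg) biological CVs, %."""

    cvi: float = Field(gt=0)
    cvg: float = Field(gt=0)


class TestDefinition(_Model):
    test_code: str = Field(min_length=1)
    name: str = ""
    unit: str = ""
    precision: int = Field(default=1, ge=0)  # reported decimal places
    av_range: Interval = Field(default_factory=Interval)
    critical_limits: Interval = Field(default_factory=Interval)
    hil_thresholds: dict[str, float] = Field(default_factory=dict)
    delta: Optional[DeltaConfig] = None
    biovar: Optional[BiologicalVariation] = None
    age_groups_included: list[tuple[float, float]] = Field(
        default_factory=lambda: [(0.0, 150.0)]
    )
    flags_blocking: set[str] = Field(default_factory=set)
    analyzers_included: set[str] = Field(default_factory=set)

    @field_validator("hil_thresholds")
    @classmethod
    def _hil_keys(cls, v: dict[str, float]) -> dict[str, float]:
        allowed = {"hemolysis", "icterus", "lipemia"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unknown HIL index name(s): {sorted(bad)}")
        for k, t in v.items():
            if t < 0 or not math.isfinite(t):
                raise ValueError(f"HIL threshold for {k} must be finite and >= 0")
        return v

    @field_validator("age_groups_included")
    @classmethod
    def _age_groups(cls, v: list[tuple[float, float]]) -> list[tuple[float, float]]:
        for lo, hi in v:
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid age group [{lo}, {hi})")
        ordered = sorted(v)
        for (lo1, hi1), (lo2, _hi2) in zip(ordered, ordered[1:]):
            if lo2 < hi1:
                raise ValueError("age groups overlap")
        return v

    @model_validator(mode="after")
    def _rcv_needs_biovar(self) -> "TestDefinition":
        if self.delta is not None and self.delta.mode is DeltaMode.rcv and self.biovar is None:
            raise ValueError(
                f"test {self.test_code}: delta mode 'rcv' requires biovar (CVi)"
            )
        return self

    def age_included(self, age_years: float) -> bool:
        """Membership in any [min, max) included age band."""
        return any(lo <= age_years < hi for lo, hi in self.age_groups_included)


class ConsistencyRule(_Model):
    """Per-sample plausibility band on the ratio of two related tests."""

    rule_id: str = Field(min_length=1)
    numerator_test: str = Field(min_length=1)
    denominator_test: str = Field(min_length=1)
    limits: Interval

    @model_validator(mode="after")
    def _checks(self) -> "ConsistencyRule":
        if self.numerator_test == self.denominator_test:
            raise ValueError("numerator and denominator tests must differ")
        if self.limits.low is not None and self.limits.high is not None:
            if not self.limits.low < self.limits.high:
                raise ValueError("consistency limits must satisfy low < high")
        return self


class QCPolicy(_Model):
    """Internal-QC gating: failed or stale QC disables autovalidation."""

    test_code: str = Field(min_length=1)
    in_control: bool = True
    last_pass_time: dt.datetime
    max_age_hours: float = Field(gt=0)


class ReportMetadata(_Model):
    """Header fields for verification spreadsheets and audit reports."""

    institution: str = ""
    department: str = ""
    instrument: str = ""
    lis_version: str = ""
    verifier: str = ""


class EngineConfig(_Model):
    schema_version: int = SCHEMA_VERSION
    mode: EngineMode = EngineMode.manual_trigger
    kill_switch: bool = False
    tests: dict[str, TestDefinition]
    consistency_rules: list[ConsistencyRule] = Field(default_factory=list)
    qc_policies: dict[str, QCPolicy] = Field(default_factory=dict)
    metadata: ReportMetadata = Field(default_factory=ReportMetadata)

    @model_validator(mode="before")
    @classmethod
    def _listy_inputs(cls, data):
        # YAML documents naturally carry tests/qc policies as lists;
        # key them by test_code for O(1) lookup.
        if isinstance(data, dict):
            tests = data.get("tests")
            if isinstance(tests, list):
                data = dict(data)
                data["tests"] = {
                    t.get("test_code", f"#{i}") if isinstance(t, dict) else t.test_code: t
                    for i, t in enumerate(tests)
                }
            qc = data.get("qc_policies")
            if isinstance(qc, list):
                data = dict(data)
                data["qc_policies"] = {
                    p.get("test_code", f"#{i}") if isinstance(p, dict) else p.test_code: p
                    for i, p in enumerate(qc)
                }
        return data

    @model_validator(mode="after")
    def _cross_refs(self) -> "EngineConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unrecognized schema_version {self.schema_version} "
                f"(expected {SCHEMA_VERSION})"
            )
        problems = []
        for code, t in self.tests.items():
            if code != t.test_code:
                problems.append(f"tests[{code}]: key does not match test_code {t.test_code}")
        for r in self.consistency_rules:
            for ref in (r.numerator_test, r.denominator_test):
                if ref not in self.tests:
                    problems.append(
                        f"consistency_rules[{r.rule_id}]: references undefined test {ref!r}"
                    )
        for code in self.qc_policies:
            if code not in self.tests:
                problems.append(f"qc_policies[{code}]: references undefined test {code!r}")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def load_config(source) -> EngineConfig:
    """Load and validate an EngineConfig from YAML/JSON text, a path, or a dict.

    Raises ConfigError on parse failure or any invariant violation; the
    message lists every violation with the path to the offending field.
    """
    if isinstance(source, EngineConfig):
        return source
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml", ".json"))
    ):
        try:
            text = Path(source).read_text(encoding="utf-8")
        except OSError as e:
            raise ConfigError(f"cannot read config file {source}: {e}") from e
    elif isinstance(source, str):
        text = source
    else:
        text = None

    if text is not None:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ConfigError(f"config does not parse: {e}") from e
    else:
        data = source
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    try:
        return EngineConfig.model_validate(data)
    except ValidationError as e:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from e


def dump_config(config: EngineConfig) -> str:
    """Serialize an EngineConfig to canonical YAML (round-trips via load_config)."""
    data = config.model_dump(mode="json")
    return yaml.safe_dump(data, sort_keys=True, default_flow_style=False)


def age_at(patient: PatientInfo, when: dt.datetime) -> Optional[float]:
    """Patient age in fractional calendar years at `when`.

    Returns None when date_of_birth is absent.  Whole years are counted by
    calendar anniversaries; the fractional part is elapsed days since the
    last anniversary divided by the length of the current anniversary year,
    so an exact N-year anniversary gives exactly N.0.
    """
    dob = patient.date_of_birth
    if dob is None:
        return None
    ref = when.date()
    if dob > ref:
        raise ValueError(f"date_of_birth {dob} is after {ref}")

    def anniversary(year: int) -> dt.date:
        # Feb 29 birthdays fall on Mar 1 in common years.
        if dob.month == 2 and dob.day == 29 and not calendar.isleap(year):
            return dt.date(year, 3, 1)
        return dt.date(year, dob.month, dob.day)

    years = ref.year - dob.year
    last = anniversary(dob.year + years)
    if last > ref:
        years -= 1
        last = anniversary(dob.year + years)
    nxt = anniversary(dob.year + years + 1)
    span = (nxt - last).days
    return years + (ref - last).days / span
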