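"""Synthetic laboratory result streams with known ground truth.

Emulates stationary homeostasis: each patient carries a homeostatic
set-point drawn from the population distribution with between-subject
spread CVg, and serial results vary about that set-point with combined
within-subject biological and analytical spread sqrt(CVi^2 + CVa^2).
Both layers are log-normal — analyte concentrations are positive — with
percent CVs mapped to log-scale sigma via sigma = sqrt(ln(1 + cv^2)) and
the population mean preserved on the natural scale.

Preanalytical errors can be injected with per-type rates and exact
ground-truth labels: sample swaps (misidentification), dilution by
intravenous fluids, and hemolysis.  Errors are mutually exclusive per
record so every label is unambiguous.  Everything is deterministic under
a fixed seed.
"""

from __future__ import annotations

import datetime as dt
import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .config import HILIndices, PatientInfo, ResultRecord, Sex

__all__ = [
    "TestSim",
    "SimSpec",
    "ErrorLabel",
    "GroundTruth",
    "simulate_population",
    "inject_swap",
    "inject_dilution",
    "inject_hemolysis",
    "record_key",
]


class TestSim(BaseModel):
    """Population model for one simulated measurand."""

    model_config = ConfigDict(extra="forbid")

    test_code: str = Field(min_length=1)
    mean: float = Field(gt=0)  # population mean, test units
    cvg: float = Field(ge=0)  # between-subject biological CV, %
    cvi: float = Field(ge=0)  # within-subject biological CV, %
    cva: float = Field(default=0.0, ge=0)  # analytical CV, %
    unit: str = ""


class SimSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(ge=1)
    tests: list[TestSim] = Field(min_length=1)
    draws_per_patient: int = Field(ge=1)
    mean_interval_hours: float = Field(default=24.0, gt=0)
    start: dt.datetime = dt.datetime(2025, 1, 1, 8, 0)
    error_rates: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _rates(self) -> "SimSpec":
        allowed = {"swap", "dilution", "hemolysis", "flag"}
        for k, v in self.error_rates.items():
            if k not in allowed:
                raise ValueError(f"unknown error type {k!r}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"error rate for {k} must be in [0, 1], got {v}")
        return self


class ErrorLabel(str, enum.Enum):
    clean = "clean"
    swapped = "swapped"
    diluted = "diluted"
    hemolyzed = "hemolyzed"
    flagged = "flagged"


def record_key(record: ResultRecord) -> tuple[str, str]:
    """Stable identity of one result: (sample_id, test_code)."""
    return (record.sample_id, record.test_code)


@dataclass
class GroundTruth:
    """Per-record error labels; every injected error labeled exactly once."""

    labels: dict[tuple[str, str], ErrorLabel] = field(default_factory=dict)
    swap_partners: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)

    def label(self, record: ResultRecord) -> ErrorLabel:
        return self.labels.get(record_key(record), ErrorLabel.clean)

    def count(self, label: ErrorLabel) -> int:
        return sum(1 for v in self.labels.values() if v is label)


def _log_sigma(cv_percent: float) -> float:
    cv = cv_percent / 100.0
    return math.sqrt(math.log1p(cv * cv))


def simulate_population(spec: SimSpec) -> tuple[list[ResultRecord], GroundTruth]:
    """Generate a clean serial result stream for a patient population.

    Each patient's set-point for test t is mean_t * LN(-sg^2/2, sg) with
    sg from CVg; each serial draw multiplies the set-point by
    LN(-sw^2/2, sw) with sw from sqrt(CVi^2 + CVa^2), so the expectation
    equals the population mean.  Timestamps are strictly increasing per
    patient (exponential inter-draw intervals, floored at 30 minutes).
    Deterministic for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ResultRecord] = []
    truth = GroundTruth()
    sexes = rng.integers(0, 2, size=spec.n_patients)
    ages_days = rng.integers(20 * 365, 80 * 365, size=spec.n_patients)
    for i in range(spec.n_patients):
        pid = f"P{i + 1:05d}"
        patient = PatientInfo(
            patient_id=pid,
            date_of_birth=spec.start.date() - dt.timedelta(days=int(ages_days[i])),
            sex=Sex.male if sexes[i] == 0 else Sex.female,
        )
        setpoints = {}
        for t in spec.tests:
            sg = _log_sigma(t.cvg)
            setpoints[t.test_code] = t.mean * math.exp(
                rng.normal(-0.5 * sg * sg, sg) if sg > 0 else 0.0
            )
        when = spec.start
        for d in range(spec.draws_per_patient):
            gap = max(0.5, rng.exponential(spec.mean_interval_hours))
            when = when + dt.timedelta(hours=float(gap))
            sample_id = f"S{i + 1:05d}-{d + 1:03d}"
            for t in spec.tests:
                sw = _log_sigma(math.hypot(t.cvi, t.cva))
                mult = math.exp(rng.normal(-0.5 * sw * sw, sw)) if sw > 0 else 1.0
                rec = ResultRecord(
                    sample_id=sample_id,
                    test_code=t.test_code,
                    value=setpoints[t.test_code] * mult,
                    unit=t.unit,
                    timestamp=when,
                    patient=patient,
                    hil=HILIndices(hemolysis=0.0, icterus=0.0, lipemia=0.0),
                )
                records.append(rec)
                truth.labels[record_key(rec)] = ErrorLabel.clean
    return records, truth


def _clean_indices(records: list[ResultRecord], truth: GroundTruth) -> list[int]:
    return [
        i for i, r in enumerate(records)
        if truth.labels.get(record_key(r), ErrorLabel.clean) is ErrorLabel.clean
    ]


def inject_swap(
    records: list[ResultRecord],
    truth: GroundTruth,
    rate: float,
    seed: int,
) -> tuple[list[ResultRecord], GroundTruth]:
    """Exchange values between same-test results of different patients.

    Emulates sample misidentification: the two records keep their own
    sample ids and timestamps, only the measured values move.  Both
    records of a pair are labeled ``swapped`` with partner references.
    Approximately ``rate`` of the clean records end up swapped.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(records)
    by_test: dict[str, list[int]] = {}
    for i in _clean_indices(out, truth):
        by_test.setdefault(out[i].test_code, []).append(i)
    for code in sorted(by_test):
        idx = by_test[code]
        n_pairs = (
            len(idx) // 2 if rate == 1.0 else int(round(rate * len(idx) / 2.0))
        )
        if n_pairs == 0:
            continue
        pool = [idx[k] for k in rng.permutation(len(idx))]
        taken = 0
        while taken < n_pairs and len(pool) >= 2:
            i = pool.pop(0)
            j = None
            for k, cand in enumerate(pool):
                if out[cand].patient.patient_id != out[i].patient.patient_id:
                    j = pool.pop(k)
                    break
            if j is None:  # only same-patient records left
                break
            vi, vj = out[i].value, out[j].value
            out[i] = out[i].model_copy(update={"value": vj})
            out[j] = out[j].model_copy(update={"value": vi})
            ki, kj = record_key(out[i]), record_key(out[j])
            truth.labels[ki] = ErrorLabel.swapped
            truth.labels[kj] = ErrorLabel.swapped
            truth.swap_partners[ki] = kj
            truth.swap_partners[kj] = ki
            taken += 1
    return out, truth


def inject_dilution(
    records: list[ResultRecord],
    truth: GroundTruth,
    rate: float,
    factor: float,
    seed: int,
) -> tuple[list[ResultRecord], GroundTruth]:
    """Multiply selected clean values by ``factor`` (IV-fluid dilution)."""
    if not 0.0 < factor < 1.0:
        raise ValueError(f"dilution factor must be in (0, 1), got {factor}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = list(records)
    for i in _clean_indices(out, truth):
        if rng.random() < rate and out[i].value is not None:
            out[i] = out[i].model_copy(update={"value": out[i].value * factor})
            truth.labels[record_key(out[i])] = ErrorLabel.diluted
    return out, truth


def inject_hemolysis(
    records: list[ResultRecord],
    truth: GroundTruth,
    rate: float,
    index_value: float,
    seed: int,
) -> tuple[list[ResultRecord], GroundTruth]:
    """Set the hemolysis index of selected clean records to ``index_value``.

    Pair with a configuration whose hemolysis threshold lies below
    ``index_value`` so the interference rule holds the injected records.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if index_value < 0:
        raise ValueError("index_value must be >= 0")
    rng = np.random.default_rng(seed)
    out = list(records)
    for i in _clean_indices(out, truth):
        if rng.random() < rate:
            hil = out[i].hil.model_copy(update={"hemolysis": float(index_value)})
            out[i] = out[i].model_copy(update={"hil": hil})
            truth.labels[record_key(out[i])] = ErrorLabel.hemolyzed
    return out, truth
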