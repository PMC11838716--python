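"""File readers and writers for result streams, decisions and manifests.

Dialect fixed for cross-locale reproducibility of clinical audit
artifacts: UTF-8, comma-separated, ISO-8601 timestamps, dot decimal
separator.  Analyzer flags are semicolon-joined within their column.

Record CSV columns::

    sample_id,test_code,value,unit,timestamp,patient_id,date_of_birth,
    sex,location,patient_class,analyzer,flags,hemolysis,icterus,lipemia

``value``, ``date_of_birth``, HIL indices and ``analyzer`` may be empty.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from . import __version__
from .config import (
    EngineConfig,
    HILIndices,
    PatientClass,
    PatientInfo,
    ResultRecord,
    Sex,
    dump_config,
)
from .outcomes import ValidationDecision
from .simulate import ErrorLabel, GroundTruth, record_key

__all__ = [
    "RECORD_COLUMNS",
    "DataError",
    "read_records",
    "write_records",
    "write_decisions",
    "write_ground_truth",
    "RunManifest",
    "build_manifest",
    "write_manifest",
]

RECORD_COLUMNS = [
    "sample_id", "test_code", "value", "unit", "timestamp",
    "patient_id", "date_of_birth", "sex", "location", "patient_class",
    "analyzer", "flags", "hemolysis", "icterus", "lipemia",
]


class DataError(ValueError):
    """A data file failed to parse; the message carries the line number."""


def _opt_float(s: str) -> Optional[float]:
    s = s.strip()
    return float(s) if s else None


def read_records(path: str | Path) -> list[ResultRecord]:
    """Read a result-stream CSV; malformed rows raise DataError with line numbers."""
    path = Path(path)
    records: list[ResultRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ("sample_id", "test_code", "timestamp", "patient_id")
                   if c not in header]
        if missing:
            raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                dob = (row.get("date_of_birth") or "").strip()
                records.append(ResultRecord(
                    sample_id=row["sample_id"].strip(),
                    test_code=row["test_code"].strip(),
                    value=_opt_float(row.get("value") or ""),
                    unit=(row.get("unit") or "").strip(),
                    timestamp=dt.datetime.fromisoformat(row["timestamp"].strip()),
                    patient=PatientInfo(
                        patient_id=row["patient_id"].strip(),
                        date_of_birth=dt.date.fromisoformat(dob) if dob else None,
                        sex=Sex((row.get("sex") or "unknown").strip() or "unknown"),
                        location=(row.get("location") or "").strip() or None,
                        patient_class=PatientClass(
                            (row.get("patient_class") or "unknown").strip() or "unknown"),
                    ),
                    analyzer=(row.get("analyzer") or "").strip() or None,
                    flags=[f for f in (row.get("flags") or "").split(";") if f],
                    hil=HILIndices(
                        hemolysis=_opt_float(row.get("hemolysis") or ""),
                        icterus=_opt_float(row.get("icterus") or ""),
                        lipemia=_opt_float(row.get("lipemia") or ""),
                    ),
                ))
            except (KeyError, ValueError) as e:
                raise DataError(f"{path}:{lineno}: bad record: {e}") from e
    return records


def write_records(records: Iterable[ResultRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RECORD_COLUMNS)
        for r in records:
            p = r.patient
            w.writerow([
                r.sample_id, r.test_code,
                "" if r.value is None else repr(r.value),
                r.unit, r.timestamp.isoformat(),
                p.patient_id,
                p.date_of_birth.isoformat() if p.date_of_birth else "",
                p.sex.value, p.location or "", p.patient_class.value,
                r.analyzer or "", ";".join(r.flags),
                "" if r.hil.hemolysis is None else repr(r.hil.hemolysis),
                "" if r.hil.icterus is None else repr(r.hil.icterus),
                "" if r.hil.lipemia is None else repr(r.hil.lipemia),
            ])
    return path


def write_decisions(decisions: Iterable[ValidationDecision], path: str | Path) -> Path:
    """Per-record decisions with every rule outcome, as an audit CSV.

    The ``decision`` column is the explicit autovalidated marker available
    to downstream systems; it is stored here, never on the clinical report.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "test_code", "value", "timestamp", "patient_id",
                    "decision", "critical_alert", "hold_reasons", "rule_outcomes"])
        for d in decisions:
            r = d.record
            outcomes = ";".join(
                f"{o.rule.value}={o.status.value}"
                + (f":{o.reason_code}" if o.reason_code else "")
                for o in d.outcomes
            )
            holds = ";".join(f"{o.rule.value}:{o.reason_code}" for o in d.holds)
            w.writerow([
                r.sample_id, r.test_code,
                "" if r.value is None else repr(r.value),
                r.timestamp.isoformat(), r.patient.patient_id,
                d.decision.value, "yes" if d.critical_alert else "no",
                holds, outcomes,
            ])
    return path


def write_ground_truth(records: list[ResultRecord], truth: GroundTruth,
                       path: str | Path) -> Path:
    """Sidecar CSV of per-record error labels for a simulated stream."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "test_code", "label", "swap_partner"])
        for r in records:
            key = record_key(r)
            label = truth.labels.get(key, ErrorLabel.clean)
            partner = truth.swap_partners.get(key)
            w.writerow([r.sample_id, r.test_code, label.value,
                        f"{partner[0]}/{partner[1]}" if partner else ""])
    return path


@dataclass
class RunManifest:
    """Audit record of one engine run: inputs, digests, seed, version."""

    command: str
    config_hash: str = ""
    inputs: dict[str, str] = field(default_factory=dict)  # name -> sha256
    seed: Optional[int] = None
    started_at: str = ""
    tool_version: str = __version__


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(command: str, config: Optional[EngineConfig] = None,
                   input_paths: Iterable[str | Path] = (),
                   seed: Optional[int] = None) -> RunManifest:
    m = RunManifest(
        command=command,
        seed=seed,
        started_at=dt.datetime.now().isoformat(timespec="seconds"),
    )
    if config is not None:
        m.config_hash = hashlib.sha256(dump_config(config).encode()).hexdigest()
    for p in input_paths:
        p = Path(p)
        m.inputs[p.name] = _sha256_file(p)
    return m


def write_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n", encoding="utf-8")
    return path
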