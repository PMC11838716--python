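"""Rule verdicts and the overall autovalidate-or-hold decision."""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .config import ResultRecord

__all__ = ["RuleId", "Status", "Decision", "RuleOutcome", "ValidationDecision"]


class RuleId(str, enum.Enum):
    kill_switch = "kill_switch"
    demographics = "demographics"
    flags = "flags"
    hil = "hil"
    critical = "critical"
    av_range = "av_range"
    delta = "delta"
    consistency = "consistency"
    qc = "qc"


class Status(str, enum.Enum):
    PASS = "PASS"
    HOLD = "HOLD"
    SKIP = "SKIP"  # rule preconditions unmet (e.g. no prior for delta)


class Decision(str, enum.Enum):
    AUTOVALIDATED = "AUTOVALIDATED"
    HELD = "HELD"


@dataclass(frozen=True)
class RuleOutcome:
    """One rule's verdict on one result."""

    rule: RuleId
    status: Status
    reason_code: str = ""
    detail: str = ""

    def __post_init__(self) -> None:
        if self.status is Status.HOLD and not self.reason_code:
            raise ValueError(f"HOLD outcome for {self.rule.value} requires a reason code")


@dataclass(frozen=True)
class ValidationDecision:
    """Conjunction of all rule verdicts for one result.

    AUTOVALIDATED if and only if no outcome HOLDs; SKIPped rules count as
    passes.  ``critical_alert`` mirrors the critical-limits rule so that
    critical results can be routed for immediate manual notification.
    """

    record: "ResultRecord"
    outcomes: tuple[RuleOutcome, ...]
    decision: Decision
    decided_at: dt.datetime
    critical_alert: bool = False
    notes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        any_hold = any(o.status is Status.HOLD for o in self.outcomes)
        if any_hold != (self.decision is Decision.HELD):
            raise ValueError("decision must be HELD iff some outcome HOLDs")

    @property
    def holds(self) -> tuple[RuleOutcome, ...]:
        return tuple(o for o in self.outcomes if o.status is Status.HOLD)
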