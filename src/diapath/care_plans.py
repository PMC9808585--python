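"""Self-management-support plans for patients and physicians.

Plans are generated by firing the rule base over the patient's facts with
the assigned management level seeded in, then splitting the derived plan
items by role: the patient's daily-task plan (self-monitoring, medication
guidance, lifestyle guidance, health education) and the physician's
intervention plan (the regular follow-up cadence plus one intervention item
per open warning).  Every item is traceable to the rule that produced it.

Medication knowledge is deliberately shallow: drug-class review suggestions
only, never dosing.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

from .config import EngineConfig
from .domain_model import FactBase, PatientProfile
from .pathway_engine import ManagementLevel
from .rulebase import Assertion, Rule, RuleBaseError, infer

PATIENT_TASKS = frozenset(
    {"self_monitoring", "medication_guidance", "lifestyle_guidance", "health_education"}
)
PHYSICIAN_TASKS = frozenset(
    {"regular_follow_up", "abnormal_attention", "compliance_management", "risk_assessment"}
)

#: plan-item contents that must never co-occur (rule-base sanity check)
EXCLUSIVE_CONTENT_PAIRS: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class PlanItem:
    task: str
    content: str
    source_rule: str
    frequency_per_week: int | None = None
    interval_days: int | None = None

    def __post_init__(self) -> None:
        freq = self.frequency_per_week
        if freq is not None and freq <= 0:
            raise ValueError("frequency_per_week must be positive")
        if self.interval_days is not None and self.interval_days <= 0:
            raise ValueError("interval_days must be positive")


@dataclass(frozen=True)
class CarePlan:
    patient_id: str
    role: str  #: "patient" or "physician"
    level: ManagementLevel
    issued: dt.date
    items: tuple[PlanItem, ...]

    def __post_init__(self) -> None:
        if self.role not in ("patient", "physician"):
            raise ValueError(f"unknown plan role {self.role!r}")
        allowed = PATIENT_TASKS if self.role == "patient" else PHYSICIAN_TASKS
        for item in self.items:
            if item.task not in allowed:
                raise ValueError(
                    f"{self.role} plan cannot contain {item.task!r} items"
                )

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "role": self.role,
            "level": int(self.level),
            "issued": self.issued.isoformat(),
            "items": [
                {k: v for k, v in item.__dict__.items() if v is not None}
                for item in self.items
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def _plan_items_from(result, exclusive=EXCLUSIVE_CONTENT_PAIRS) -> list[PlanItem]:
    """Collect derived plan_item assertions, resolving each to its rule."""
    items = []
    contents = set()
    for a in sorted(
        (a for a in result.assertions if a.predicate == "plan_item"),
        key=lambda a: repr(a.value),
    ):
        payload = a.value_as_dict()
        source = next(
            (
                f.rule_id
                for f in result.trace
                if any(x.predicate == "plan_item" and x.value == a.value for x in f.assertions)
            ),
            "unknown",
        )
        items.append(
            PlanItem(
                task=payload["task"],
                content=payload["content"],
                frequency_per_week=payload.get("frequency_per_week"),
                source_rule=source,
            )
        )
        contents.add(payload["content"])
    for a, b in exclusive:
        if a in contents and b in contents:
            raise RuleBaseError(f"contradictory plan items fired: {a!r} vs {b!r}")
    return items


def _infer_with_level(
    facts: FactBase | Mapping[str, Any], level: ManagementLevel | int, rules: Sequence[Rule]
):
    f = dict(facts.facts if isinstance(facts, FactBase) else facts)
    return infer(f, rules, seed_assertions=[Assertion("management_level", int(level))])


def build_patient_plan(
    profile: PatientProfile,
    level: ManagementLevel,
    facts: FactBase | Mapping[str, Any],
    rules: Sequence[Rule],
    config: EngineConfig | None = None,
    issued: dt.date | None = None,
) -> CarePlan:
    """The patient's self-management plan for the assigned level.

    Glucose self-monitoring defaults to 1/3/7 days per week for levels
    1/2/3 (from the self_monitoring rules; ``config.monitoring_days_per_week``
    overrides); blood-pressure monitoring is daily iff the patient is
    hypertensive.  Medication, lifestyle and education items come from rule
    firings.  Deterministic for identical inputs.
    """
    cfg = config or EngineConfig()
    result = _infer_with_level(facts, level, rules)
    items = [i for i in _plan_items_from(result) if i.task in PATIENT_TASKS]
    if cfg.monitoring_days_per_week is not None:
        freq = cfg.monitoring_days_per_week[int(level)]
        items = [
            PlanItem(
                task=i.task,
                content=i.content,
                source_rule=i.source_rule,
                frequency_per_week=freq if "FBG" in i.content else i.frequency_per_week,
            )
            if i.task == "self_monitoring"
            else i
            for i in items
        ]
    return CarePlan(
        patient_id=profile.patient_id,
        role="patient",
        level=ManagementLevel(int(level)),
        issued=issued or dt.date.today(),
        items=tuple(items),
    )


def build_physician_plan(
    level: ManagementLevel,
    config: EngineConfig | None = None,
    rules: Sequence[Rule] = (),
    open_warnings: Sequence = (),
    patient_id: str = "",
    issued: dt.date | None = None,
) -> CarePlan:
    """The physician's intervention plan: regular cadence + warning items."""
    cfg = config or EngineConfig()
    interval = cfg.interval_for(int(level))
    source = "config:followup_interval_days"
    for r in rules:
        if r.module == "regular_follow_up" and any(
            a.predicate == "followup_interval_days" and a.value == interval
            for a in r.actions
        ) and any(
            c.predicate == "management_level" and c.operand == int(level)
            for c in r.conditions
        ):
            source = r.rule_id
            break
    items = [
        PlanItem(
            task="regular_follow_up",
            content=f"regular follow-up every {interval} days",
            interval_days=interval,
            source_rule=source,
        )
    ]
    for w in open_warnings:
        items.append(
            PlanItem(
                task="abnormal_attention",
                content=f"intervene on open {w.type}",
                interval_days=cfg.abnormal_followup_lag_days,
                source_rule="engine:abnormal_attention",
            )
        )
    if not patient_id and open_warnings:
        patient_id = getattr(open_warnings[0], "patient_id", "")
    return CarePlan(
        patient_id=patient_id,
        role="physician",
        level=ManagementLevel(int(level)),
        issued=issued or dt.date.today(),
        items=tuple(items),
    )


def medication_guidance(
    facts: FactBase | Mapping[str, Any],
    rules: Sequence[Rule],
    level: ManagementLevel | int | None = None,
) -> list[PlanItem]:
    """Drug-class suggestions derived from the medication-guidance rules.

    Class-level only (e.g. first-line oral agent review, intensification
    flag at level 3, antihypertensive review) — never dosing.  Raises
    :class:`RuleBaseError` if mutually exclusive classes fire together.
    """
    if level is not None:
        result = _infer_with_level(facts, level, rules)
    else:
        f = dict(facts.facts if isinstance(facts, FactBase) else facts)
        result = infer(f, rules)
    return [i for i in _plan_items_from(result) if i.task == "medication_guidance"]


def refresh_plan(old: CarePlan, new: CarePlan) -> CarePlan:
    """Plan refresh on a level change.

    Frequency-bearing items are replaced by the new plan's; completed-task
    history lives in the task log and is untouched by construction.
    """
    if old.patient_id != new.patient_id or old.role != new.role:
        raise ValueError("refresh must keep patient and role")
    return new
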