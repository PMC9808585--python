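"""Closed-loop pathway state machine.

A diabetic patient enters the pathway at enrollment: cardiovascular risk is
assessed, a management level is assigned from the glycemic picture, and a
regular follow-up schedule starts.  Levels: routine level 1 for stable
glucose (within control targets), routine level 2 for above-target glucose,
intensive level 3 strictly above the intensive fasting-glucose bound
(default 11.1 mmol/L).  The condition is re-evaluated every 30 days on
trailing-30-day means; an upgrade to a more intensive level is immediate,
while a downgrade requires two consecutive in-target evaluations
(hysteresis).  Day by day, :func:`step` runs warning detection, compliance
checking, due follow-ups and due re-evaluations, and emits a replayable
event log.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from typing import Mapping, Sequence

import pandas as pd

from .config import EngineConfig
from .domain_model import (
    Disease,
    FactBase,
    Measurement,
    PatientProfile,
    TaskRecord,
    build_factbase,
)
from .rulebase import Rule, infer
from .variation import (
    ComplianceStatus,
    FollowUpEvent,
    Warning,
    compliance_rate,
    detect_warnings,
    trigger_variation_followups,
)

log = logging.getLogger(__name__)


class ReplayError(RuntimeError):
    """The event stream moved backwards in time (corrupted replay)."""


class ManagementLevel(IntEnum):
    LEVEL_1_ROUTINE = 1
    LEVEL_2_ROUTINE = 2
    LEVEL_3_INTENSIVE = 3


class PathwayTask(str, Enum):
    """The nine pathway tasks, partitioned into three task sets."""

    RISK_ASSESSMENT = "risk_assessment"
    HIERARCHICAL_MANAGEMENT = "hierarchical_management"
    SELF_MONITORING = "self_monitoring"
    REGULAR_FOLLOW_UP = "regular_follow_up"
    ABNORMAL_ATTENTION = "abnormal_attention"
    COMPLIANCE_MANAGEMENT = "compliance_management"
    MEDICATION_GUIDANCE = "medication_guidance"
    LIFESTYLE_GUIDANCE = "lifestyle_guidance"
    HEALTH_EDUCATION = "health_education"


REGULAR_TASK_SET = frozenset(
    {
        PathwayTask.RISK_ASSESSMENT,
        PathwayTask.HIERARCHICAL_MANAGEMENT,
        PathwayTask.SELF_MONITORING,
        PathwayTask.REGULAR_FOLLOW_UP,
    }
)
VARIATION_TASK_SET = frozenset(
    {PathwayTask.ABNORMAL_ATTENTION, PathwayTask.COMPLIANCE_MANAGEMENT}
)
SUPPORT_TASK_SET = frozenset(
    {
        PathwayTask.MEDICATION_GUIDANCE,
        PathwayTask.LIFESTYLE_GUIDANCE,
        PathwayTask.HEALTH_EDUCATION,
    }
)


@dataclass(frozen=True)
class Event:
    """A non-follow-up engine event (level change, plan refresh, data flag)."""

    patient_id: str
    date: dt.date
    event_type: str  #: one of level_change | plan_refresh | flag
    detail: str = ""


@dataclass
class PathwayState:
    """A patient's current position in the management pathway."""

    patient_id: str
    profile: PatientProfile
    level: ManagementLevel
    cycle_start: dt.date
    level_history: list[tuple[dt.date, ManagementLevel]] = field(default_factory=list)
    next_regular_followup: dt.date | None = None
    open_warnings: list[Warning] = field(default_factory=list)
    compliance_low: bool = False
    risk_factors: tuple[str, ...] = ()

    # replay bookkeeping
    regular_schedule: list[dt.date] = field(default_factory=list)
    pending_followups: list[FollowUpEvent] = field(default_factory=list)
    last_abnormal_followup: dt.date | None = None
    last_compliance_followup: dt.date | None = None
    last_eval_date: dt.date | None = None
    last_step_date: dt.date | None = None
    last_events: list = field(default_factory=list)
    downgrade_streak: int = 0
    as_of: dt.date | None = None
    records: list[Measurement] = field(default_factory=list)
    tasks: list[TaskRecord] = field(default_factory=list)
    _recent_tasks: list[TaskRecord] = field(default_factory=list)


def _facts_of(facts: FactBase | Mapping[str, object]) -> dict:
    return dict(facts.facts if isinstance(facts, FactBase) else facts)


def assess_level(
    facts: FactBase | Mapping[str, object],
    rules: Sequence[Rule] = (),
    config: EngineConfig | None = None,
) -> ManagementLevel:
    """Assign a management level from the current glycemic facts.

    The hierarchical-management rules decide when they fire; otherwise the
    configured thresholds apply directly: intensive strictly above
    ``intensive_fbg``, level 1 when every known glucose fact is within
    target, level 2 otherwise.  With no glucose facts at all the patient is
    held at level 2 and an insufficient-data flag is logged.
    """
    cfg = config or EngineConfig()
    f = _facts_of(facts)
    if rules:
        lvl = infer(f, rules).single("management_level")
        if lvl is not None:
            return ManagementLevel(int(lvl))
    fbg = f.get("latest_FBG")
    pbg = f.get("latest_PBG")
    if fbg is None and pbg is None:
        log.info("%s: insufficient glycemic data; holding level 2", f.get("patient_id", "?"))
        return ManagementLevel.LEVEL_2_ROUTINE
    if fbg is not None and fbg > cfg.intensive_fbg:
        return ManagementLevel.LEVEL_3_INTENSIVE
    if (fbg is None or fbg <= cfg.target_fbg) and (pbg is None or pbg <= cfg.target_pbg):
        return ManagementLevel.LEVEL_1_ROUTINE
    return ManagementLevel.LEVEL_2_ROUTINE


def schedule_regular_followups(
    level: ManagementLevel | int,
    cycle_start: dt.date,
    horizon_days: int,
    config: EngineConfig | None = None,
) -> list[dt.date]:
    """Regular follow-up dates at ``cycle_start + k * interval(level)``.

    Monthly (30 d) for levels 2 and 3, once per 90-day cycle for level 1.
    """
    if horizon_days < 0:
        raise ValueError("horizon_days must be nonnegative")
    cfg = config or EngineConfig()
    interval = cfg.interval_for(int(level))
    return [
        cycle_start + dt.timedelta(days=k * interval)
        for k in range(1, horizon_days // interval + 1)
    ]


def enroll(
    profile: PatientProfile,
    initial_records: Sequence[Measurement],
    config: EngineConfig | None = None,
    rules: Sequence[Rule] = (),
) -> PathwayState:
    """Admit a diabetic patient: risk assessment, level assignment, schedule."""
    cfg = config or EngineConfig()
    if Disease.DIABETES not in profile.diseases:
        raise ValueError("pathway admits only diabetic patients")
    facts = build_factbase(profile, initial_records, (), profile.enrollment_date)
    risk = tuple(sorted(infer(facts, rules).values("risk_factor"))) if rules else ()
    level = assess_level(facts, rules, cfg)
    schedule = schedule_regular_followups(level, profile.enrollment_date, cfg.cycle_days, cfg)
    state = PathwayState(
        patient_id=profile.patient_id,
        profile=profile,
        level=level,
        cycle_start=profile.enrollment_date,
        level_history=[(profile.enrollment_date, level)],
        next_regular_followup=schedule[0] if schedule else None,
        risk_factors=risk,
        regular_schedule=schedule,
        last_eval_date=profile.enrollment_date,
        records=list(initial_records),
    )
    return state


def _mean_based_facts(facts: dict) -> dict:
    """Re-evaluation view: trailing-30-day means stand in for latest readings."""
    out = dict(facts)
    for kind in ("FBG", "PBG", "SBP", "DBP"):
        mean = facts.get(f"mean_{kind}_30d")
        if mean is not None:
            out[f"latest_{kind}"] = mean
        else:
            out.pop(f"latest_{kind}", None)
    return out


def reevaluate(
    state: PathwayState,
    records: Sequence[Measurement],
    date: dt.date,
    config: EngineConfig | None = None,
    rules: Sequence[Rule] = (),
) -> PathwayState:
    """Periodic condition review on trailing-30-day mean glucose/pressure.

    Upgrades take effect immediately (the latest fasting reading above the
    intensive bound also forces level 3 on its own); a downgrade needs
    ``downgrade_confirmations`` consecutive in-target evaluations.  With no
    usable glycemic data the level is left unchanged and a flag is logged.
    """
    cfg = config or EngineConfig()
    facts = build_factbase(state.profile, records, state.tasks, date).facts
    view = _mean_based_facts(facts)
    if view.get("latest_FBG") is None and view.get("latest_PBG") is None:
        log.info("%s: no glycemic data at re-evaluation; level unchanged", state.patient_id)
        state.last_eval_date = date
        return state
    target = assess_level(view, rules, cfg)
    latest_fbg = facts.get("latest_FBG")
    if latest_fbg is not None and latest_fbg > cfg.intensive_fbg:
        target = ManagementLevel.LEVEL_3_INTENSIVE

    if target > state.level:
        _transition(state, target, date, cfg)
        state.downgrade_streak = 0
    elif target == state.level:
        state.downgrade_streak = 0
    else:
        state.downgrade_streak += 1
        if state.downgrade_streak >= cfg.downgrade_confirmations:
            _transition(state, target, date, cfg)
            state.downgrade_streak = 0
    state.last_eval_date = date
    return state


def _transition(
    state: PathwayState, level: ManagementLevel, date: dt.date, cfg: EngineConfig
) -> None:
    state.level = level
    state.level_history.append((date, level))
    horizon = (state.cycle_start + dt.timedelta(days=cfg.cycle_days) - date).days
    future = schedule_regular_followups(level, date, max(horizon, 0), cfg)
    state.regular_schedule = [d for d in state.regular_schedule if d <= date] + future
    state.next_regular_followup = future[0] if future else None


def step(
    state: PathwayState,
    day_records: Sequence[Measurement],
    day_tasks: Sequence[TaskRecord],
    date: dt.date,
    rules: Sequence[Rule] = (),
    config: EngineConfig | None = None,
) -> tuple[PathwayState, list]:
    """Advance one patient one day; returns the events the day produced.

    Emits completed follow-ups (regular, abnormal-attention, compliance),
    new warnings, level changes and plan refreshes.  Deterministic, and
    idempotent for a repeated call on the same date.  A date earlier than
    the previous step raises :class:`ReplayError`.
    """
    cfg = config or EngineConfig()
    if state.last_step_date is not None:
        if date < state.last_step_date:
            raise ReplayError(
                f"{state.patient_id}: step date {date} precedes {state.last_step_date}"
            )
        if date == state.last_step_date:
            return state, list(state.last_events)

    state.as_of = date
    state.records.extend(day_records)
    state.tasks.extend(day_tasks)
    state._recent_tasks.extend(day_tasks)
    prune_before = date - dt.timedelta(days=cfg.compliance_window_days)
    state._recent_tasks = [
        t for t in state._recent_tasks if t.scheduled_date > prune_before
    ]
    events: list = []

    # 1. physician completes booked variation follow-ups due today
    due = [e for e in state.pending_followups if e.date <= date]
    state.pending_followups = [e for e in state.pending_followups if e.date > date]
    for ev in due:
        events.append(ev)
        if ev.category == "abnormal_attention":
            state.last_abnormal_followup = date
            state.open_warnings = []
        elif ev.category == "compliance":
            state.last_compliance_followup = date

    # 2. regular follow-up due today
    if date in state.regular_schedule:
        events.append(
            FollowUpEvent(
                patient_id=state.patient_id,
                date=date,
                category="regular",
                detail=f"level {int(state.level)} scheduled contact",
            )
        )
        upcoming = [d for d in state.regular_schedule if d > date]
        state.next_regular_followup = upcoming[0] if upcoming else None

    # 3. abnormal-attention warnings from today's records
    warnings = detect_warnings(day_records, cfg)
    for w in warnings:
        events.append(w)
        state.open_warnings.append(w)

    # 4. compliance status over the trailing window
    comp: ComplianceStatus | None = None
    if state.tasks:
        comp = compliance_rate(
            state._recent_tasks,
            date,
            cfg.compliance_window_days,
            cfg.low_compliance_rate,
            patient_id=state.patient_id,
            last_compliance_followup=state.last_compliance_followup,
        )
        state.compliance_low = comp.low

    # 5. book extra follow-ups the day's variations require
    state.pending_followups.extend(
        trigger_variation_followups(warnings, comp, state, cfg)
    )

    # 6. periodic re-evaluation
    elapsed = (date - state.cycle_start).days
    if elapsed > 0 and elapsed % cfg.reeval_interval_days == 0:
        before = state.level
        reevaluate(state, state.records, date, cfg, rules)
        if state.level != before:
            events.append(
                Event(
                    patient_id=state.patient_id,
                    date=date,
                    event_type="level_change",
                    detail=f"{int(before)}->{int(state.level)}",
                )
            )
            events.append(
                Event(
                    patient_id=state.patient_id,
                    date=date,
                    event_type="plan_refresh",
                    detail=f"level {int(state.level)}",
                )
            )

    state.last_step_date = date
    state.last_events = list(events)
    return state, events


# ---------------------------------------------------------------------------
# event-log serialization
# ---------------------------------------------------------------------------

def event_row(ev) -> dict:
    if isinstance(ev, FollowUpEvent):
        return {
            "date": ev.date.isoformat(),
            "patient_id": ev.patient_id,
            "event_type": "followup",
            "category": ev.category,
            "detail": ev.warning_type or ev.detail,
        }
    if isinstance(ev, Warning):
        return {
            "date": ev.date.isoformat(),
            "patient_id": ev.patient_id,
            "event_type": "warning",
            "category": ev.type,
            "detail": f"{ev.triggering_measurement.kind.value}={ev.triggering_measurement.value:g}",
        }
    return {
        "date": ev.date.isoformat(),
        "patient_id": ev.patient_id,
        "event_type": ev.event_type,
        "category": "",
        "detail": ev.detail,
    }


def events_to_frame(events: Sequence) -> pd.DataFrame:
    """Event log as a DataFrame with columns date,patient_id,event_type,category,detail."""
    return pd.DataFrame(
        [event_row(e) for e in events],
        columns=["date", "patient_id", "event_type", "category", "detail"],
    )
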