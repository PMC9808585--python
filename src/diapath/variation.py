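"""Pathway-variation tasks: abnormal-attention warnings and compliance.

Two situations divert a patient from the regular schedule: an abnormal
self-monitoring reading (blood glucose, blood pressure, heart rate, or a
reported symptom — the four warning categories) and a low task-completion
rate.  Either books an extra physician follow-up on top of the regular
cadence.  Every emitted follow-up carries exactly one of the three
categories used by the retrospective accounting: ``regular``,
``abnormal_attention``, ``compliance``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import EngineConfig
from .domain_model import (
    Measurement,
    MeasurementKind,
    TaskRecord,
    completion_fraction,
)

FOLLOWUP_CATEGORIES = ("regular", "abnormal_attention", "compliance")
WARNING_TYPES = ("BG_WARNING", "BP_WARNING", "DISORDER_WARNING", "HR_WARNING")


@dataclass(frozen=True)
class Warning:
    """One abnormal-attention warning (debounced to one per type per day)."""

    patient_id: str
    type: str
    triggering_measurement: Measurement
    date: dt.date
    resolved: bool = False

    def __post_init__(self) -> None:
        if self.type not in WARNING_TYPES:
            raise ValueError(f"unknown warning type {self.type!r}")


@dataclass(frozen=True)
class ComplianceStatus:
    patient_id: str
    window_days: int
    rate: float
    low: bool
    last_compliance_followup: dt.date | None = None


@dataclass(frozen=True)
class FollowUpEvent:
    """A physician contact, categorized for the retrospective accounting."""

    patient_id: str
    date: dt.date
    category: str
    warning_type: str | None = None  #: set for abnormal_attention events
    detail: str = ""

    def __post_init__(self) -> None:
        if self.category not in FOLLOWUP_CATEGORIES:
            raise ValueError(f"unknown follow-up category {self.category!r}")


def _warning_type_for(m: Measurement, cfg: EngineConfig) -> str | None:
    k, v = m.kind, m.value
    if k in (MeasurementKind.FBG, MeasurementKind.PBG):
        if v < cfg.bg_critical_low or v >= cfg.bg_critical_high:
            return "BG_WARNING"
        if k is MeasurementKind.FBG and v >= cfg.fbg_warning_high:
            return "BG_WARNING"
    elif k is MeasurementKind.SBP:
        if v >= cfg.sbp_warning_high or v < cfg.sbp_warning_low:
            return "BP_WARNING"
    elif k is MeasurementKind.DBP:
        if v >= cfg.dbp_warning_high:
            return "BP_WARNING"
    elif k is MeasurementKind.HR:
        if v < cfg.hr_warning_low or v > cfg.hr_warning_high:
            return "HR_WARNING"
    elif k is MeasurementKind.SYMPTOM:
        if v >= cfg.symptom_warning_severity:
            return "DISORDER_WARNING"
    return None


def detect_warnings(
    day_records: Sequence[Measurement], config: EngineConfig | None = None
) -> list[Warning]:
    """Scan one day's records and emit at most one warning per type per day.

    Default bounds: BG below 3.9 or at/above 16.7 mmol/L (FBG additionally
    at/above 13.9); SBP at/above 160 or below 90 mmHg, DBP at/above 100;
    heart rate below 50 or above 120 bpm; symptom severity grade ≥ 2.
    """
    cfg = config or EngineConfig()
    seen: set[tuple[str, str, dt.date]] = set()
    out: list[Warning] = []
    for rec in day_records:
        wtype = _warning_type_for(rec, cfg)
        if wtype is None:
            continue
        key = (rec.patient_id, wtype, rec.timestamp.date())
        if key in seen:
            continue
        seen.add(key)
        out.append(
            Warning(
                patient_id=rec.patient_id,
                type=wtype,
                triggering_measurement=rec,
                date=rec.timestamp.date(),
            )
        )
    return out


def compliance_rate(
    tasks: Iterable[TaskRecord],
    as_of: dt.date,
    window_days: int = 7,
    low_threshold: float = 0.5,
    patient_id: str | None = None,
    last_compliance_followup: dt.date | None = None,
) -> ComplianceStatus:
    """Task-completion rate over ``(as_of - window, as_of]``.

    Nothing scheduled in the window counts as fully compliant.  ``low`` is
    true when the rate falls strictly below ``low_threshold``.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    tasks = list(tasks)
    if patient_id is None:
        patient_id = tasks[0].patient_id if tasks else "unknown"
    rate = completion_fraction(tasks, as_of, window_days)
    return ComplianceStatus(
        patient_id=patient_id,
        window_days=window_days,
        rate=rate,
        low=rate < low_threshold,
        last_compliance_followup=last_compliance_followup,
    )


def trigger_variation_followups(
    warnings: Sequence[Warning],
    compliance: ComplianceStatus | None,
    state,  # PathwayState; duck-typed to avoid a circular import
    config: EngineConfig | None = None,
) -> list[FollowUpEvent]:
    """Book the extra physician contacts a day's variations require.

    One abnormal-attention follow-up the next day covers all of the day's
    unresolved warnings (and is suppressed while a recent or pending
    abnormal contact already covers the patient); a compliance follow-up is
    booked at most once per compliance window.
    """
    cfg = config or EngineConfig()
    out: list[FollowUpEvent] = []

    unresolved = [w for w in warnings if not w.resolved]
    if unresolved:
        day = unresolved[0].date
        due = day + dt.timedelta(days=cfg.abnormal_followup_lag_days)
        gap = dt.timedelta(days=cfg.abnormal_followup_min_gap_days)
        last = getattr(state, "last_abnormal_followup", None)
        pending = any(
            e.category == "abnormal_attention" for e in getattr(state, "pending_followups", [])
        )
        if not pending and (last is None or due - last >= gap):
            # the contact is attributed to the day's most salient warning
            lead = unresolved[0]
            out.append(
                FollowUpEvent(
                    patient_id=lead.patient_id,
                    date=due,
                    category="abnormal_attention",
                    warning_type=lead.type,
                    detail=";".join(sorted({w.type for w in unresolved})),
                )
            )

    if compliance is not None and compliance.low:
        base = getattr(state, "as_of", None)
        if not isinstance(base, dt.date):
            base = warnings[0].date if warnings else dt.date.today()
        due = base + dt.timedelta(days=cfg.abnormal_followup_lag_days)
        last = compliance.last_compliance_followup
        pending = any(
            e.category == "compliance" for e in getattr(state, "pending_followups", [])
        )
        if not pending and (
            last is None or (due - last).days >= compliance.window_days
        ):
            out.append(
                FollowUpEvent(
                    patient_id=compliance.patient_id,
                    date=due,
                    category="compliance",
                    detail=f"completion rate {compliance.rate:.2f} over {compliance.window_days} d",
                )
            )
    return out
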