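"""Core patient record types and per-patient fact extraction.

The pathway engine reasons over a small, flat *fact base*: the latest value
of each monitored vital, trailing-30-day means, comorbidity flags and a
short-window task-completion rate, all frozen at a decision date.  This
module defines the validated record types (profile, measurement, task log
entry) and the deterministic extraction of that fact base.

Conventions: timestamps are ISO 8601; scheduling is day-granular while
measurement ordering uses full date-times; "month" means 30 days.  Units are
implied by the measurement kind (mmol/L for glucose, mmHg for pressure, bpm,
kg) and never converted — out-of-convention input is rejected, not coerced.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

MEAN_WINDOW_DAYS = 30
COMPLIANCE_WINDOW_DAYS = 7
SYMPTOM_WINDOW_DAYS = 7

#: the nine pathway tasks, grouped into the three task sets
REGULAR_TASKS = frozenset(
    {"risk_assessment", "hierarchical_management", "self_monitoring", "regular_follow_up"}
)
VARIATION_TASKS = frozenset({"abnormal_attention", "compliance_management"})
SUPPORT_TASKS = frozenset({"medication_guidance", "lifestyle_guidance", "health_education"})
ALL_TASKS = REGULAR_TASKS | VARIATION_TASKS | SUPPORT_TASKS

#: task names that represent a physician contact (used for
#: ``days_since_last_followup``)
FOLLOWUP_TASKS = frozenset({"regular_follow_up", "abnormal_attention", "compliance_management"})


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Disease(str, Enum):
    DIABETES = "diabetes"
    HYPERTENSION = "hypertension"


class SpecialGroup(str, Enum):
    ADOLESCENT = "adolescent"
    DISABILITY = "disability"


class MeasurementKind(str, Enum):
    FBG = "FBG"  #: fasting blood glucose, mmol/L (pre-meal)
    PBG = "PBG"  #: 2-h postprandial blood glucose, mmol/L
    SBP = "SBP"  #: systolic blood pressure, mmHg
    DBP = "DBP"  #: diastolic blood pressure, mmHg
    HR = "HR"  #: heart rate, bpm
    WEIGHT = "WEIGHT"  #: body weight, kg
    SYMPTOM = "SYMPTOM"  #: coded discomfort report, severity grade 1-3


BG_KINDS = (MeasurementKind.FBG, MeasurementKind.PBG)
MEANED_KINDS = (
    MeasurementKind.FBG,
    MeasurementKind.PBG,
    MeasurementKind.SBP,
    MeasurementKind.DBP,
)


def _as_date(value: dt.date | dt.datetime | str) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _as_datetime(value: dt.date | dt.datetime | str) -> dt.datetime:
    if isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.date):
        return dt.datetime.combine(value, dt.time.min)
    return dt.datetime.fromisoformat(str(value))


@dataclass(frozen=True)
class PatientProfile:
    """Demographics, comorbidities and enrollment anchor for one patient.

    Only patients with type 2 diabetes are admitted to the pathway; the
    comorbidity set may additionally contain hypertension.  ``bmi`` and
    ``smoker`` are optional risk-assessment inputs.
    """

    patient_id: str
    sex: Sex
    age: int
    diseases: frozenset[Disease]
    enrollment_date: dt.date
    special_group: frozenset[SpecialGroup] = frozenset()
    bmi: float | None = None
    smoker: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "diseases", frozenset(Disease(d) for d in self.diseases))
        object.__setattr__(
            self, "special_group", frozenset(SpecialGroup(g) for g in self.special_group)
        )
        object.__setattr__(self, "enrollment_date", _as_date(self.enrollment_date))
        if Disease.DIABETES not in self.diseases:
            raise ValidationError(f"{self.patient_id}: pathway admits only diabetic patients")
        if self.age <= 0:
            raise ValidationError(f"{self.patient_id}: age must be positive")
        if SpecialGroup.ADOLESCENT in self.special_group and self.age >= 18:
            raise ValidationError(f"{self.patient_id}: adolescent implies age < 18")
        if self.bmi is not None and self.bmi <= 0:
            raise ValidationError(f"{self.patient_id}: bmi must be positive")

    @property
    def has_hypertension(self) -> bool:
        return Disease.HYPERTENSION in self.diseases


@dataclass(frozen=True)
class Measurement:
    """One time-stamped physiological observation."""

    patient_id: str
    kind: MeasurementKind
    value: float
    timestamp: dt.datetime
    #: free-text meal context for glucose readings; stored, never validated
    meal_context: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MeasurementKind(self.kind))
        object.__setattr__(self, "timestamp", _as_datetime(self.timestamp))
        object.__setattr__(self, "value", float(self.value))


@dataclass(frozen=True)
class TaskRecord:
    """One scheduled pathway task and its completion status."""

    patient_id: str
    task: str
    scheduled_date: dt.date
    completed: bool
    completed_date: dt.date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheduled_date", _as_date(self.scheduled_date))
        if self.completed_date is not None:
            object.__setattr__(self, "completed_date", _as_date(self.completed_date))
        if self.task not in ALL_TASKS:
            raise ValidationError(f"unknown pathway task {self.task!r}")
        if self.completed:
            if self.completed_date is None:
                raise ValidationError("completed task requires completed_date")
            if self.completed_date < self.scheduled_date - dt.timedelta(days=1):
                raise ValidationError("completed_date more than 1 day before schedule")


@dataclass(frozen=True)
class FactBase:
    """Ground facts about one patient frozen at a decision date.

    ``facts`` maps predicate name to value; at most one fact per predicate,
    each derived exclusively from records time-stamped at or before
    ``as_of`` (no lookahead).
    """

    patient_id: str
    as_of: dt.date
    facts: dict[str, object]

    def get(self, predicate: str, default=None):
        return self.facts.get(predicate, default)


def validate_record(
    record: Measurement, profile: PatientProfile | None = None
) -> Measurement:
    """Return ``record`` unchanged if it satisfies the domain invariants.

    Raises :class:`ValidationError` on a nonpositive value, an unknown kind,
    a symptom severity outside grades 1-3, or (when ``profile`` is given) a
    timestamp preceding enrollment.
    """
    if not isinstance(record.kind, MeasurementKind):
        raise ValidationError(f"unknown measurement kind {record.kind!r}")
    if not record.value > 0:
        raise ValidationError(
            f"{record.patient_id}: nonpositive {record.kind.value} value {record.value}"
        )
    if record.kind is MeasurementKind.SYMPTOM and int(record.value) not in (1, 2, 3):
        raise ValidationError(f"symptom severity must be grade 1-3, got {record.value}")
    if profile is not None:
        if record.patient_id != profile.patient_id:
            raise ValidationError("record does not belong to profile")
        if record.timestamp.date() < profile.enrollment_date:
            raise ValidationError(
                f"{record.patient_id}: measurement predates enrollment"
            )
    return record


def completion_fraction(
    tasks: Iterable[TaskRecord], as_of: dt.date, window_days: int = COMPLIANCE_WINDOW_DAYS
) -> float:
    """Completed/scheduled over tasks scheduled in ``(as_of - window, as_of]``.

    A window with nothing scheduled counts as fully compliant (1.0).
    """
    lo = as_of - dt.timedelta(days=window_days)
    scheduled = [t for t in tasks if lo < t.scheduled_date <= as_of]
    if not scheduled:
        return 1.0
    done = sum(1 for t in scheduled if t.completed)
    return done / len(scheduled)


def build_factbase(
    profile: PatientProfile,
    records: Sequence[Measurement],
    tasks: Sequence[TaskRecord] = (),
    as_of: dt.date | None = None,
) -> FactBase:
    """Extract the ground fact base for one patient at a decision date.

    Deterministic and insensitive to input ordering: records are sorted by
    timestamp (ties keep the later-read record, with a warning).  Only
    records with ``timestamp <= as_of`` (end of day) contribute.  With no
    usable records the fact base carries only profile-derived facts.
    """
    as_of = _as_date(as_of if as_of is not None else dt.date.today())
    cutoff = dt.datetime.combine(as_of, dt.time.max)

    usable: list[tuple[dt.datetime, int, Measurement]] = []
    for order, rec in enumerate(records):
        if rec.patient_id != profile.patient_id:
            raise ValidationError(
                f"record for {rec.patient_id} passed to fact base of {profile.patient_id}"
            )
        if rec.timestamp <= cutoff:
            usable.append((rec.timestamp, order, rec))
    usable.sort(key=lambda t: (t[0], t[1]))

    facts: dict[str, object] = {
        "has_hypertension": profile.has_hypertension,
        "age": profile.age,
        "sex": profile.sex.value,
    }
    if profile.bmi is not None:
        facts["bmi"] = profile.bmi
    if profile.smoker:
        facts["smoker"] = True

    latest: dict[MeasurementKind, Measurement] = {}
    for ts, _, rec in usable:
        prev = latest.get(rec.kind)
        if prev is not None and prev.timestamp == ts:
            log.warning(
                "%s: duplicate %s at %s; keeping last-read value",
                profile.patient_id,
                rec.kind.value,
                ts.isoformat(),
            )
        latest[rec.kind] = rec
    for kind, rec in latest.items():
        facts[f"latest_{kind.value}"] = rec.value

    window_start = dt.datetime.combine(
        as_of - dt.timedelta(days=MEAN_WINDOW_DAYS), dt.time.max
    )
    for kind in MEANED_KINDS:
        vals = [
            rec.value
            for ts, _, rec in usable
            if rec.kind is kind and ts > window_start
        ]
        if vals:
            facts[f"mean_{kind.value}_{MEAN_WINDOW_DAYS}d"] = sum(vals) / len(vals)

    symptom_start = dt.datetime.combine(
        as_of - dt.timedelta(days=SYMPTOM_WINDOW_DAYS), dt.time.max
    )
    severities = [
        int(rec.value)
        for ts, _, rec in usable
        if rec.kind is MeasurementKind.SYMPTOM and ts > symptom_start
    ]
    if severities:
        facts["symptom_present"] = True
        facts["symptom_severity"] = max(severities)

    if tasks:
        facts["compliance_rate_7d"] = completion_fraction(
            tasks, as_of, COMPLIANCE_WINDOW_DAYS
        )
        contact_dates = [
            t.completed_date
            for t in tasks
            if t.task in FOLLOWUP_TASKS and t.completed and t.completed_date is not None
            and t.completed_date <= as_of
        ]
        if contact_dates:
            facts["days_since_last_followup"] = (as_of - max(contact_dates)).days

    return FactBase(patient_id=profile.patient_id, as_of=as_of, facts=facts)


# ---------------------------------------------------------------------------
# file interchange: CSV for measurements, JSON for profiles and task logs
# ---------------------------------------------------------------------------

def read_measurements_csv(path: str | Path) -> list[Measurement]:
    """Read measurements from CSV columns patient_id,kind,value,timestamp."""
    df = pd.read_csv(path, dtype={"patient_id": str, "kind": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            validate_record(
                Measurement(
                    patient_id=row.patient_id,
                    kind=MeasurementKind(row.kind),
                    value=float(row.value),
                    timestamp=_as_datetime(row.timestamp),
                )
            )
        )
    return out


def write_measurements_csv(records: Sequence[Measurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "kind": [r.kind.value for r in records],
            "value": [r.value for r in records],
            "timestamp": [r.timestamp.isoformat() for r in records],
        }
    ).to_csv(path, index=False)


def profile_to_dict(p: PatientProfile) -> dict:
    return {
        "patient_id": p.patient_id,
        "sex": p.sex.value,
        "age": p.age,
        "diseases": sorted(d.value for d in p.diseases),
        "enrollment_date": p.enrollment_date.isoformat(),
        "special_group": sorted(g.value for g in p.special_group),
        "bmi": p.bmi,
        "smoker": p.smoker,
    }


def profile_from_dict(d: dict) -> PatientProfile:
    return PatientProfile(
        patient_id=d["patient_id"],
        sex=Sex(d["sex"]),
        age=int(d["age"]),
        diseases=frozenset(Disease(x) for x in d["diseases"]),
        enrollment_date=_as_date(d["enrollment_date"]),
        special_group=frozenset(SpecialGroup(x) for x in d.get("special_group", [])),
        bmi=d.get("bmi"),
        smoker=bool(d.get("smoker", False)),
    )


def read_profiles_json(path: str | Path) -> list[PatientProfile]:
    return [profile_from_dict(d) for d in json.loads(Path(path).read_text())]


def write_profiles_json(profiles: Sequence[PatientProfile], path: str | Path) -> None:
    Path(path).write_text(json.dumps([profile_to_dict(p) for p in profiles], indent=1))


def read_tasks_json(path: str | Path) -> list[TaskRecord]:
    out = []
    for d in json.loads(Path(path).read_text()):
        out.append(
            TaskRecord(
                patient_id=d["patient_id"],
                task=d["task"],
                scheduled_date=_as_date(d["scheduled_date"]),
                completed=bool(d["completed"]),
                completed_date=_as_date(d["completed_date"])
                if d.get("completed_date")
                else None,
            )
        )
    return out


def write_tasks_json(tasks: Sequence[TaskRecord], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "patient_id": t.patient_id,
                    "task": t.task,
                    "scheduled_date": t.scheduled_date.isoformat(),
                    "completed": t.completed,
                    "completed_date": t.completed_date.isoformat()
                    if t.completed_date
                    else None,
                }
                for t in tasks
            ],
            indent=1,
        )
    )
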