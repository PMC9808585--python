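"""Synthetic telehealth cohort generator and closed-loop runner.

Emulates a 272-patient, 90-day managed T2DM cohort: 42.6% with comorbid
hypertension, 65.1% with abnormal baseline glucose, 69.8% abnormal baseline
pressure among the hypertensive, mean age 58.24 (SD 9.81), 54% male — and
intervention-responsive trajectories in which each completed physician
follow-up lowers the patient's latent glucose/pressure means from the next
30-day month onward.

Each patient draws from an independent pseudo-random stream keyed by
``(seed, patient_index)``, so changing the cohort size never perturbs
existing patients.  The generator co-runs the real pathway engine day by
day: the patient's current self-management plan decides which measurements
are attempted, adherence decides which are completed, and the engine's
emitted follow-ups feed back into the trajectories (a compliance contact
also boosts subsequent adherence).  Because the engine is deterministic in
its inputs, :func:`run_closed_loop` replaying the generated records
reproduces the generation-time event log exactly.

What this does *not* emulate: real measurement cadence, dropout,
pharmacokinetics, or seasonal/weekday structure; latent means are
piecewise-constant per month and floored at physiologic values.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import EngineConfig
from .domain_model import (
    Disease,
    Measurement,
    MeasurementKind,
    PatientProfile,
    Sex,
    SpecialGroup,
    TaskRecord,
)
from .pathway_engine import PathwayState, enroll, step
from .rulebase import Rule, load_default_rules
from .variation import FollowUpEvent

DEFAULT_START = dt.date(2020, 1, 6)  # a Monday; weeks align with day index


@dataclass
class CohortConfig:
    """Cohort composition; defaults reproduce the study-population mix."""

    seed: int
    n_patients: int = 272
    p_hypertension: float = 0.426
    p_abnormal_bg: float = 0.651
    p_abnormal_bp_given_htn: float = 0.698
    p_male: float = 0.54
    age_mean: float = 58.24
    age_sd: float = 9.81
    p_adolescent: float = 0.025
    p_disability: float = 0.007
    horizon_days: int = 90
    start_date: dt.date = DEFAULT_START

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "p_hypertension",
            "p_abnormal_bg",
            "p_abnormal_bp_given_htn",
            "p_male",
            "p_adolescent",
            "p_disability",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TrajectoryModel:
    """Latent trajectories and their response to physician contact.

    Baselines are per-patient latent means (mmol/L, mmHg, bpm); readings add
    i.i.d. noise.  ``effect_*`` is the latent-mean reduction applied per
    completed follow-up, taking effect from the following 30-day month;
    floors keep repeated interventions physiologic.  Adherence is the daily
    probability of completing a scheduled task, boosted by
    ``adherence_boost`` (capped) after each compliance follow-up.
    """

    # baseline latent means (normal / abnormal mixtures)
    fbg_normal_mean: float = 6.1
    fbg_normal_sd: float = 0.5
    fbg_normal_range: tuple[float, float] = (5.0, 6.9)
    fbg_abnormal_mean: float = 9.3
    fbg_abnormal_sd: float = 1.6
    fbg_abnormal_range: tuple[float, float] = (7.2, 12.5)
    pbg_offset_mean: float = 2.8
    pbg_offset_sd: float = 0.8
    sbp_normal_mean: float = 124.0
    sbp_normal_sd: float = 6.0
    sbp_abnormal_mean: float = 152.0
    sbp_abnormal_sd: float = 8.0
    sbp_abnormal_range: tuple[float, float] = (142.0, 175.0)
    dbp_normal_mean: float = 77.0
    dbp_normal_sd: float = 5.0
    dbp_abnormal_mean: float = 94.0
    dbp_abnormal_sd: float = 6.0
    dbp_abnormal_range: tuple[float, float] = (88.0, 110.0)
    hr_mean: float = 76.0
    hr_sd: float = 8.0

    # per-reading measurement noise (sd)
    noise_fbg: float = 0.6
    noise_pbg: float = 0.9
    noise_sbp: float = 7.0
    noise_dbp: float = 5.0
    noise_hr: float = 7.0

    # latent-mean reduction per completed follow-up, applied monthly
    effect_fbg: float = 0.8
    effect_pbg: float = 1.0
    effect_sbp: float = 6.0
    effect_dbp: float = 5.0

    # physiologic floors for the latent means
    floor_fbg: float = 4.5
    floor_pbg: float = 6.5
    floor_sbp: float = 112.0
    floor_dbp: float = 68.0

    # behaviour
    p_adherence: float = 0.7
    adherence_boost: float = 0.2
    adherence_cap: float = 0.95
    p_symptom_day: float = 0.004
    symptom_severity_probs: tuple[float, float, float] = (0.5, 0.35, 0.15)
    p_hr_event: float = 0.003

    def __post_init__(self) -> None:
        for name in ("effect_fbg", "effect_pbg", "effect_sbp", "effect_dbp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("noise_fbg", "noise_pbg", "noise_sbp", "noise_dbp", "noise_hr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 < self.p_adherence <= 1.0:
            raise ValueError("p_adherence must be in (0, 1]")


@dataclass
class SimulatedCohort:
    profiles: list[PatientProfile]
    measurements: list[Measurement]
    tasks: list[TaskRecord]
    #: latent group assignments per patient (for composition checks)
    assignments: pd.DataFrame
    config: CohortConfig
    model: TrajectoryModel


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


_MONITOR_FREQ = {1: 1, 2: 3, 3: 7}  # days/week by level; mirrors SM-01..03


def _monitor_freq(level: int, engine_cfg: EngineConfig) -> int:
    if engine_cfg.monitoring_days_per_week is not None:
        return engine_cfg.monitoring_days_per_week[int(level)]
    return _MONITOR_FREQ[int(level)]


def _simulate_patient(
    index: int,
    config: CohortConfig,
    model: TrajectoryModel,
    rules: Sequence[Rule],
    engine_cfg: EngineConfig,
):
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, index]))
    pid = f"P{index:04d}"
    m = model

    htn = rng.random() < config.p_hypertension
    bg_abnormal = rng.random() < config.p_abnormal_bg
    bp_abnormal = htn and rng.random() < config.p_abnormal_bp_given_htn
    sex = Sex.MALE if rng.random() < config.p_male else Sex.FEMALE
    adolescent = rng.random() < config.p_adolescent
    disability = rng.random() < config.p_disability
    if adolescent:
        age = int(rng.integers(13, 18))
    else:
        # adult mean adjusted so the cohort mean matches the configured mean
        adult_mean = (config.age_mean - config.p_adolescent * 15.5) / (
            1.0 - config.p_adolescent
        )
        age = int(round(_truncnorm(rng, adult_mean, config.age_sd, 18, 95)))
    groups = set()
    if adolescent:
        groups.add(SpecialGroup.ADOLESCENT)
    if disability:
        groups.add(SpecialGroup.DISABILITY)
    profile = PatientProfile(
        patient_id=pid,
        sex=sex,
        age=age,
        diseases=frozenset(
            {Disease.DIABETES} | ({Disease.HYPERTENSION} if htn else set())
        ),
        enrollment_date=config.start_date,
        special_group=frozenset(groups),
        bmi=float(np.round(_truncnorm(rng, 25.5, 3.5, 17, 40), 1)),
        smoker=bool(rng.random() < 0.25),
    )

    # latent baselines
    if bg_abnormal:
        fbg = _truncnorm(rng, m.fbg_abnormal_mean, m.fbg_abnormal_sd, *m.fbg_abnormal_range)
    else:
        fbg = _truncnorm(rng, m.fbg_normal_mean, m.fbg_normal_sd, *m.fbg_normal_range)
    offset = max(0.5, rng.normal(m.pbg_offset_mean, m.pbg_offset_sd))
    pbg = fbg + offset
    if not bg_abnormal:
        pbg = min(pbg, 9.8)  # keep the normal group within the PBG target
    if bp_abnormal:
        sbp = _truncnorm(rng, m.sbp_abnormal_mean, m.sbp_abnormal_sd, *m.sbp_abnormal_range)
        dbp = _truncnorm(rng, m.dbp_abnormal_mean, m.dbp_abnormal_sd, *m.dbp_abnormal_range)
    else:
        sbp = rng.normal(m.sbp_normal_mean, m.sbp_normal_sd)
        dbp = rng.normal(m.dbp_normal_mean, m.dbp_normal_sd)
    hr = rng.normal(m.hr_mean, m.hr_sd)
    fbg0, pbg0, sbp0, dbp0 = fbg, pbg, sbp, dbp

    def reading(kind: MeasurementKind, latent: float, noise: float, date: dt.date) -> Measurement:
        value = max(0.1, latent + rng.normal(0.0, noise) if noise > 0 else latent)
        return Measurement(
            patient_id=pid,
            kind=kind,
            value=float(np.round(value, 1)),
            timestamp=dt.datetime.combine(date, dt.time(8, 0)),
        )

    # day-0 initial assessment: BG for everyone, BP for hypertensive patients
    day0 = config.start_date
    initial = [
        reading(MeasurementKind.FBG, fbg, m.noise_fbg, day0),
        reading(MeasurementKind.PBG, pbg, m.noise_pbg, day0),
    ]
    if htn:
        initial += [
            reading(MeasurementKind.SBP, sbp, m.noise_sbp, day0),
            reading(MeasurementKind.DBP, dbp, m.noise_dbp, day0),
        ]
    state = enroll(profile, initial, engine_cfg, rules)

    measurements = list(initial)
    tasks: list[TaskRecord] = []
    events: list = []
    p_adh = m.p_adherence
    month_followups = 0

    for d in range(1, config.horizon_days + 1):
        date = config.start_date + dt.timedelta(days=d)
        if d > 1 and (d - 1) % 30 == 0:
            # previous month's completed follow-ups take effect now
            fbg = max(m.floor_fbg, fbg - m.effect_fbg * month_followups)
            pbg = max(m.floor_pbg, pbg - m.effect_pbg * month_followups)
            sbp = max(m.floor_sbp, sbp - m.effect_sbp * month_followups)
            dbp = max(m.floor_dbp, dbp - m.effect_dbp * month_followups)
            month_followups = 0

        day_records: list[Measurement] = []
        day_tasks: list[TaskRecord] = []

        def schedule(task: str) -> bool:
            done = bool(rng.random() < p_adh)
            day_tasks.append(
                TaskRecord(
                    patient_id=pid,
                    task=task,
                    scheduled_date=date,
                    completed=done,
                    completed_date=date if done else None,
                )
            )
            return done

        freq = _monitor_freq(int(state.level), engine_cfg)
        monitor_today = (d - 1) % 7 < freq
        if monitor_today and schedule("self_monitoring"):
            day_records.append(reading(MeasurementKind.FBG, fbg, m.noise_fbg, date))
            day_records.append(reading(MeasurementKind.PBG, pbg, m.noise_pbg, date))
            if not htn:
                hr_latent = hr
                if rng.random() < m.p_hr_event:
                    hr_latent = float(rng.choice([rng.uniform(38, 48), rng.uniform(122, 140)]))
                day_records.append(reading(MeasurementKind.HR, hr_latent, m.noise_hr, date))
        if htn and schedule("self_monitoring"):
            day_records.append(reading(MeasurementKind.SBP, sbp, m.noise_sbp, date))
            day_records.append(reading(MeasurementKind.DBP, dbp, m.noise_dbp, date))
            hr_latent = hr
            if rng.random() < m.p_hr_event:
                hr_latent = float(rng.choice([rng.uniform(38, 48), rng.uniform(122, 140)]))
            day_records.append(reading(MeasurementKind.HR, hr_latent, m.noise_hr, date))
        schedule("medication_guidance")
        if rng.random() < m.p_symptom_day:
            severity = int(rng.choice([1, 2, 3], p=list(m.symptom_severity_probs)))
            day_records.append(
                Measurement(
                    patient_id=pid,
                    kind=MeasurementKind.SYMPTOM,
                    value=severity,
                    timestamp=dt.datetime.combine(date, dt.time(12, 0)),
                )
            )

        state, day_events = step(state, day_records, day_tasks, date, rules, engine_cfg)
        for ev in day_events:
            if isinstance(ev, FollowUpEvent):
                month_followups += 1
                if ev.category == "compliance":
                    p_adh = min(m.adherence_cap, p_adh + m.adherence_boost)
        measurements.extend(day_records)
        tasks.extend(day_tasks)
        events.extend(day_events)

    assignment = {
        "patient_id": pid,
        "hypertension": htn,
        "bg_abnormal": bg_abnormal,
        "bp_abnormal": bp_abnormal,
        "initial_level": int(state.level_history[0][1]),
        "age": age,
        "male": sex is Sex.MALE,
        # baseline latent means, for parameter-recovery checks
        "fbg0": fbg0,
        "pbg0": pbg0,
        "sbp0": sbp0,
        "dbp0": dbp0,
    }
    return profile, measurements, tasks, assignment


def simulate_cohort(
    config: CohortConfig,
    model: TrajectoryModel | None = None,
    rules: Sequence[Rule] | None = None,
    engine_config: EngineConfig | None = None,
) -> SimulatedCohort:
    """Generate a reproducible cohort of profiles, measurements and task logs."""
    model = model or TrajectoryModel()
    rules = list(rules) if rules is not None else load_default_rules()
    engine_cfg = engine_config or EngineConfig()
    profiles, measurements, tasks, assignments = [], [], [], []
    for i in range(config.n_patients):
        p, ms, ts, a = _simulate_patient(i, config, model, rules, engine_cfg)
        profiles.append(p)
        measurements.extend(ms)
        tasks.extend(ts)
        assignments.append(a)
    return SimulatedCohort(
        profiles=profiles,
        measurements=measurements,
        tasks=tasks,
        assignments=pd.DataFrame(assignments),
        config=config,
        model=model,
    )


def run_closed_loop(
    cohort: SimulatedCohort,
    rules: Sequence[Rule] | None = None,
    engine_config: EngineConfig | None = None,
) -> tuple[list, dict[str, PathwayState]]:
    """Replay the full cohort through the pathway engine, day by day.

    Returns the complete event log and each patient's final state.  The
    engine is deterministic in its inputs, so replaying a simulated cohort
    reproduces the event stream that shaped its trajectories.
    """
    rules = list(rules) if rules is not None else load_default_rules()
    engine_cfg = engine_config or EngineConfig()
    horizon = cohort.config.horizon_days
    start = cohort.config.start_date

    recs_by_patient_day: dict[tuple[str, int], list[Measurement]] = {}
    for rec in cohort.measurements:
        day = (rec.timestamp.date() - start).days
        recs_by_patient_day.setdefault((rec.patient_id, day), []).append(rec)
    tasks_by_patient_day: dict[tuple[str, int], list[TaskRecord]] = {}
    for t in cohort.tasks:
        day = (t.scheduled_date - start).days
        tasks_by_patient_day.setdefault((t.patient_id, day), []).append(t)

    events: list = []
    states: dict[str, PathwayState] = {}
    for profile in cohort.profiles:
        pid = profile.patient_id
        state = enroll(profile, recs_by_patient_day.get((pid, 0), []), engine_cfg, rules)
        for d in range(1, horizon + 1):
            date = start + dt.timedelta(days=d)
            state, day_events = step(
                state,
                recs_by_patient_day.get((pid, d), []),
                tasks_by_patient_day.get((pid, d), []),
                date,
                rules,
                engine_cfg,
            )
            events.extend(day_events)
        states[pid] = state
    return events, states
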