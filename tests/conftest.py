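"""Shared fixtures: default rules, engine config, and cached cohort runs."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import diapath as dp

N_SEEDS = 20  # closed-loop replicates shared by the stochastic suites


@pytest.fixture(scope="session")
def rules():
    return dp.load_default_rules()

@pytest.fixture(scope="session")
def config():
    return dp.EngineConfig()


def monthly_declines(cohort, kind: str) -> pd.Series:
    """Per-patient month-1 minus month-3 mean of one vital."""
    start = cohort.config.start_date
    rows = [
        (m.patient_id, (m.timestamp.date() - start).days, m.value)
        for m in cohort.measurements
        if m.kind.value == kind
    ]
    df = pd.DataFrame(rows, columns=["pid", "day", "v"])
    df["month"] = np.maximum(df["day"], 1).sub(1).floordiv(30).add(1)
    pm = df.groupby(["pid", "month"])["v"].mean().unstack()
    if 1 not in pm.columns or 3 not in pm.columns:
        return pd.Series(dtype=float)
    return (pm[1] - pm[3]).dropna()


def summarize_run(cohort, events) -> dict:
    """Small per-seed digest retained instead of the full cohort."""
    start = cohort.config.start_date
    df = dp.events_to_frame(events)
    fu = df[df["event_type"] == "followup"].copy()
    fu["day"] = (pd.to_datetime(fu["date"]).dt.date - start).map(lambda d: d.days)
    return {
        "fbg_decline": monthly_declines(cohort, "FBG"),
        "sbp_decline": monthly_declines(cohort, "SBP"),
        "followups_by_day": fu[["patient_id", "day", "category"]],
        "intervened": set(
            fu.loc[fu["category"].isin(["abnormal_attention", "compliance"]), "patient_id"]
        ),
        "assignments": cohort.assignments,
        "model": cohort.model,
        "categories": set(fu["category"]),
        "htn_patients": {p.patient_id for p in cohort.profiles if p.has_hypertension},
    }


@pytest.fixture(scope="session")
def seed_runs():
    """Full-size (n=272, 90-day) closed-loop runs for seeds 1..N_SEEDS."""
    runs = {}
    for seed in range(1, N_SEEDS + 1):
        cohort = dp.simulate_cohort(dp.CohortConfig(seed=seed))
        events, _ = dp.run_closed_loop(cohort)
        runs[seed] = summarize_run(cohort, events)
    return runs


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient cohort plus its replayed event log, for cheap checks."""
    cohort = dp.simulate_cohort(dp.CohortConfig(seed=101, n_patients=40))
    events, states = dp.run_closed_loop(cohort)
    return cohort, events, states


@pytest.fixture
def profile():
    return dp.PatientProfile(
        patient_id="P-T1",
        sex=dp.Sex.FEMALE,
        age=61,
        diseases=frozenset({dp.Disease.DIABETES}),
        enrollment_date=dt.date(2020, 1, 6),
    )


@pytest.fixture
def htn_profile():
    return dp.PatientProfile(
        patient_id="P-T2",
        sex=dp.Sex.MALE,
        age=55,
        diseases=frozenset({dp.Disease.DIABETES, dp.Disease.HYPERTENSION}),
        enrollment_date=dt.date(2020, 1, 6),
    )


def measurement(pid, kind, value, day=0, base=dt.date(2020, 1, 6), hour=8):
    return dp.Measurement(
        patient_id=pid,
        kind=dp.MeasurementKind(kind),
        value=value,
        timestamp=dt.datetime.combine(base + dt.timedelta(days=day), dt.time(hour, 0)),
    )
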