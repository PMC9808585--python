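"""Retrospective-evaluation computations over the pathway event log.

Follow-up accounting by category (regular / abnormal-attention /
compliance) with a warning-type breakdown, per-patient follow-up means,
intervention-level classification (more than 3 contacts = high, exactly 3 =
medium, fewer = low), monthly vital-sign trends over the 90-day horizon
with a paired two-tailed t test of month 1 vs month 3, and chi-square
comparison of contingency tables.

Percentages are rounded half-up to 1 decimal and means to 2 decimals to
match conventional clinical reporting.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .domain_model import Measurement, MeasurementKind
from .pathway_engine import events_to_frame
from .variation import FOLLOWUP_CATEGORIES, WARNING_TYPES, FollowUpEvent

MONTH_DAYS = 30


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 33.97 → 34.0, 2.5 → 3 at 0 digits)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_share(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage share rounded half-up; 0 when the total is 0."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# follow-up accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FollowUpSummary:
    total: int
    counts: dict[str, int]  #: by category
    shares: dict[str, float]  #: % of total, 1 decimal half-up
    warning_counts: dict[str, int]  #: within abnormal_attention, by type
    warning_shares: dict[str, float]


def _followup_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = events_to_frame(list(events))
    return df[df["event_type"] == "followup"]


def summarize_followups(events) -> FollowUpSummary:
    """Counts and percentage shares by follow-up category (Table-style).

    Accepts the raw event list from the engine or an event-log DataFrame.
    Within the abnormal-attention category, contacts are further broken
    down by the warning type that triggered them.
    """
    df = _followup_frame(events)
    total = len(df)
    counts = {c: int((df["category"] == c).sum()) for c in FOLLOWUP_CATEGORIES}
    shares = {c: percent_share(counts[c], total) for c in FOLLOWUP_CATEGORIES}
    abn = df[df["category"] == "abnormal_attention"]
    n_abn = len(abn)
    wcounts = {w: int((abn["detail"].str.split(";").str[0] == w).sum()) for w in WARNING_TYPES}
    wshares = {w: percent_share(wcounts[w], n_abn) for w in WARNING_TYPES}
    return FollowUpSummary(
        total=total,
        counts=counts,
        shares=shares,
        warning_counts=wcounts,
        warning_shares=wshares,
    )


def mean_followups_per_patient(
    events, patient_subset: Iterable[str]
) -> tuple[float, float]:
    """Mean and SD of follow-up contacts per patient over a subset.

    Patients in the subset with zero contacts count.  Mean and SD are
    rounded half-up to 2 decimals; SD is 0 for a single patient.
    """
    patients = list(dict.fromkeys(patient_subset))
    if not patients:
        raise ValueError("patient subset must be nonempty")
    df = _followup_frame(events)
    per = df.groupby("patient_id").size()
    counts = np.array([int(per.get(p, 0)) for p in patients], dtype=float)
    mean = round_half_up(float(counts.mean()), 2)
    sd = 0.0 if len(counts) < 2 else round_half_up(float(counts.std(ddof=1)), 2)
    return mean, sd


def classify_intervention_level(count: int) -> str:
    """high (> 3 contacts), medium (exactly 3) or low (< 3)."""
    if count < 0:
        raise ValueError("follow-up count cannot be negative")
    if count > 3:
        return "high"
    if count == 3:
        return "medium"
    return "low"


# ---------------------------------------------------------------------------
# monthly trends
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthlyTrend:
    kind: str
    #: per-patient monthly means averaged over patients, by month 1..3
    patient_means: dict[int, float]
    #: plain per-reading monthly means, by month 1..3
    reading_means: dict[int, float]
    delta: float  #: month-1 mean minus month-3 mean (per-patient basis)
    t_statistic: float
    p_value: float
    n_paired: int


def monthly_trend(
    measurements: Sequence[Measurement],
    kind: MeasurementKind | str,
    cohort_subset: Iterable[str] | None = None,
    enrollment_dates: Mapping[str, dt.date] | None = None,
) -> MonthlyTrend:
    """Monthly means of one vital over the 90-day horizon and the 1-vs-3 test.

    Days since enrollment (the patient's first record when no enrollment
    map is given) are binned into 30-day months.  The primary statistic
    averages per-patient monthly means; the month-1 minus month-3 delta is
    tested with a paired two-tailed t test over patients present in both
    months.  Raises ``ValueError`` when the kind is absent or fewer than
    two months carry data.
    """
    kind = MeasurementKind(kind)
    rows = [
        (m.patient_id, m.timestamp.date(), m.value)
        for m in measurements
        if m.kind is kind
    ]
    if cohort_subset is not None:
        keep = set(cohort_subset)
        rows = [r for r in rows if r[0] in keep]
    if not rows:
        raise ValueError(f"no {kind.value} measurements in the selection")
    df = pd.DataFrame(rows, columns=["patient_id", "date", "value"])
    if enrollment_dates is None:
        start = df.groupby("patient_id")["date"].transform("min")
    else:
        start = df["patient_id"].map(enrollment_dates)
    days = (pd.to_datetime(df["date"]) - pd.to_datetime(start)).dt.days
    df["month"] = np.maximum(days, 1).sub(1).floordiv(MONTH_DAYS).add(1)
    df = df[df["month"].between(1, 3)]
    months_present = sorted(df["month"].unique())
    if len(months_present) < 2:
        raise ValueError("need data in at least two months")

    per_patient = df.groupby(["patient_id", "month"])["value"].mean().unstack("month")
    patient_means = {
        int(mo): float(per_patient[mo].mean()) for mo in per_patient.columns
    }
    reading_means = {
        int(mo): float(g["value"].mean()) for mo, g in df.groupby("month")
    }

    if 1 in per_patient.columns and 3 in per_patient.columns:
        paired = per_patient[[1, 3]].dropna()
        m1, m3 = paired[1].to_numpy(), paired[3].to_numpy()
    else:
        first, last = months_present[0], months_present[-1]
        paired = per_patient[[first, last]].dropna()
        m1, m3 = paired[first].to_numpy(), paired[last].to_numpy()
    delta = float(m1.mean() - m3.mean()) if len(m1) else float("nan")
    if len(m1) >= 2 and not np.allclose(m1, m3):
        t_stat, p_val = stats.ttest_rel(m1, m3)
    elif len(m1) >= 2:
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = float("nan"), float("nan")
    return MonthlyTrend(
        kind=kind.value,
        patient_means=patient_means,
        reading_means=reading_means,
        delta=delta,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_paired=int(len(m1)),
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_counts(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a k×m count table.

    Raises ``ValueError`` for malformed tables (fewer than 2 rows or
    columns, negative or non-integer cells, or a zero row/column margin).
    """
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a k x m contingency table with k, m >= 2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("cells must be nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin row/column")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def analysis_report(events, measurements: Sequence[Measurement]) -> dict:
    """Table-style JSON report: follow-up accounting plus vital trends."""
    summary = summarize_followups(events)
    report: dict = {
        "followups": {
            "total": summary.total,
            "counts": summary.counts,
            "shares_percent": summary.shares,
            "abnormal_breakdown_counts": summary.warning_counts,
            "abnormal_breakdown_percent": summary.warning_shares,
        },
        "trends": {},
    }
    for kind in ("FBG", "PBG", "SBP", "DBP"):
        try:
            tr = monthly_trend(measurements, kind)
        except ValueError:
            continue
        report["trends"][kind] = {
            "patient_means_by_month": {str(k): round(v, 3) for k, v in tr.patient_means.items()},
            "delta_month1_minus_month3": round(tr.delta, 3),
            "t_statistic": round(tr.t_statistic, 3),
            "p_value": float(f"{tr.p_value:.3g}"),
            "n_paired": tr.n_paired,
        }
    return report
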