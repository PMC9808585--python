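"""Engine configuration.

Every clinical threshold the pathway reacts to lives here (or in the rule
file), never in code paths.  Defaults follow the Chinese T2DM prevention and
control guidelines' control targets (FBG ≤ 7.0 mmol/L, 2-h PBG ≤ 10.0 mmol/L,
intensive management above FBG 11.1 mmol/L) and common urgent-vital-sign
conventions for the telehealth warning bounds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


@dataclass
class EngineConfig:
    """Tunable parameters of the management pathway.

    Units: blood glucose in mmol/L, blood pressure in mmHg, heart rate in
    bpm, all intervals in days.
    """

    # -- glycemic stratification -------------------------------------------
    #: strict lower bound of intensive (level-3) management on fasting glucose
    intensive_fbg: float = 11.1
    #: control target for fasting blood glucose ("stable" upper bound)
    target_fbg: float = 7.0
    #: control target for 2-h postprandial blood glucose
    target_pbg: float = 10.0

    # -- scheduling ---------------------------------------------------------
    #: regular follow-up interval per management level; level 2/3 monthly,
    #: level 1 once per 90-day cycle (guidelines mandate monthly contact only
    #: for patients with substandard glucose)
    followup_interval_days: dict[int, int] = field(
        default_factory=lambda: {1: 90, 2: 30, 3: 30}
    )
    #: length of one management cycle ("3 months" = 90 days)
    cycle_days: int = 90
    #: periodic re-evaluation cadence ("month" = 30 days)
    reeval_interval_days: int = 30
    #: consecutive in-target evaluations required before a level downgrade
    downgrade_confirmations: int = 2

    # -- abnormal-attention warning bounds ----------------------------------
    bg_critical_low: float = 3.9  #: hypoglycemia, any BG reading below
    bg_critical_high: float = 16.7  #: severe hyperglycemia, any BG at/above
    fbg_warning_high: float = 13.9  #: marked fasting hyperglycemia, at/above
    sbp_warning_high: float = 160.0
    dbp_warning_high: float = 100.0
    sbp_warning_low: float = 90.0
    hr_warning_low: float = 50.0
    hr_warning_high: float = 120.0
    symptom_warning_severity: int = 2  #: reported symptom grade triggering care

    # -- compliance management ----------------------------------------------
    compliance_window_days: int = 7
    low_compliance_rate: float = 0.5

    # -- pathway-variation follow-up behaviour ------------------------------
    #: a warning books an extra physician contact this many days later
    abnormal_followup_lag_days: int = 1
    #: at most one abnormal-attention follow-up per patient per this window;
    #: repeated warnings within the window are covered by the booked contact
    abnormal_followup_min_gap_days: int = 7

    # -- self-monitoring plan -----------------------------------------------
    #: optional override of the rule base's days-per-week monitoring
    #: frequencies by level; ``None`` defers to the self_monitoring rules
    monitoring_days_per_week: dict[int, int] | None = None

    def interval_for(self, level: int) -> int:
        return int(self.followup_interval_days[int(level)])

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "EngineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.followup_interval_days is not None:
            cfg.followup_interval_days = {
                int(k): int(v) for k, v in cfg.followup_interval_days.items()
            }
        if cfg.monitoring_days_per_week is not None:
            cfg.monitoring_days_per_week = {
                int(k): int(v) for k, v in cfg.monitoring_days_per_week.items()
            }
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "EngineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **changes: Any) -> "EngineConfig":
        cfg = dataclasses.replace(self, **changes)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 < self.target_fbg < self.intensive_fbg):
            raise ValueError("require 0 < target_fbg < intensive_fbg")
        if self.target_pbg <= 0:
            raise ValueError("target_pbg must be positive")
        for level in (1, 2, 3):
            if self.interval_for(level) <= 0:
                raise ValueError("follow-up intervals must be positive")
        if self.compliance_window_days < 1:
            raise ValueError("compliance_window_days must be >= 1")
        if not 0.0 <= self.low_compliance_rate <= 1.0:
            raise ValueError("low_compliance_rate must be in [0, 1]")


DEFAULT_CONFIG = EngineConfig()
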