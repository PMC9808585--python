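"""Level assignment, scheduling, hysteresis and the daily step loop."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

import diapath as dp
from diapath.variation import FollowUpEvent

from conftest import measurement

BASE = dt.date(2020, 1, 6)


class TestAssessLevel:
    @pytest.mark.parametrize(
        "fbg,pbg,expected",
        [
            (11.2, 8.0, 3),  # strictly above the intensive bound
            (11.1, 8.0, 2),  # boundary itself is not intensive
            (12.5, None, 3),
            (7.5, 11.0, 2),  # above target on both counts
            (6.0, 8.0, 1),  # stable on both
            (6.0, None, 1),
            (None, 11.0, 2),
        ],
    )
    def test_level_from_glycemic_facts(self, rules, config, fbg, pbg, expected):
        facts = {}
        if fbg is not None:
            facts["latest_FBG"] = fbg
        if pbg is not None:
            facts["latest_PBG"] = pbg
        assert int(dp.assess_level(facts, rules, config)) == expected

    def test_no_glycemic_data_holds_level_two(self, rules, config):
        assert int(dp.assess_level({"has_hypertension": True}, rules, config)) == 2

    def test_monotone_in_fasting_glucose(self, rules, config):
        levels = [
            int(dp.assess_level({"latest_FBG": round(v, 1), "latest_PBG": 8.0}, rules, config))
            for v in np.arange(4.0, 20.01, 0.1)
        ]
        assert all(a <= b for a, b in zip(levels, levels[1:]))


class TestEnroll:
    def test_high_initial_glucose_enters_intensive(self, profile, rules, config):
        state = dp.enroll(profile, [measurement("P-T1", "FBG", 12.5)], config, rules)
        assert state.level is dp.ManagementLevel.LEVEL_3_INTENSIVE
        assert state.level_history[0] == (BASE, state.level)
        assert state.next_regular_followup == BASE + dt.timedelta(days=30)

    def test_stable_initial_glucose_enters_level_one(self, profile, rules, config):
        recs = [measurement("P-T1", "FBG", 6.0), measurement("P-T1", "PBG", 8.0)]
        state = dp.enroll(profile, recs, config, rules)
        assert state.level is dp.ManagementLevel.LEVEL_1_ROUTINE
        assert state.next_regular_followup == BASE + dt.timedelta(days=90)

    def test_risk_factors_collected_at_enrollment(self, htn_profile, rules, config):
        state = dp.enroll(htn_profile, [measurement("P-T2", "FBG", 8.0)], config, rules)
        assert "hypertension" in state.risk_factors


class TestScheduler:
    @pytest.mark.parametrize(
        "level,horizon,expected",
        [(2, 90, 3), (3, 90, 3), (1, 90, 1), (2, 0, 0), (2, 29, 0), (1, 89, 0)],
    )
    def test_counts_over_horizon(self, config, level, horizon, expected):
        dates = dp.schedule_regular_followups(level, BASE, horizon, config)
        assert len(dates) == expected

    def test_conservation_floor_rule(self, config):
        for level in (1, 2, 3):
            interval = config.interval_for(level)
            for horizon in (0, 29, 30, 31, 60, 89, 90, 181, 365):
                dates = dp.schedule_regular_followups(level, BASE, horizon, config)
                assert len(dates) == horizon // interval

    def test_dates_are_multiples_of_interval(self, config):
        dates = dp.schedule_regular_followups(2, BASE, 90, config)
        assert dates == [BASE + dt.timedelta(days=k) for k in (30, 60, 90)]


def _state(profile, rules, config, fbg=12.5):
    return dp.enroll(profile, [measurement(profile.patient_id, "FBG", fbg)], config, rules)


class TestReevaluate:
    def test_downgrade_requires_two_consecutive_stable_reviews(self, profile, rules, config):
        state = _state(profile, rules, config, fbg=12.5)
        recs = list(state.records)
        # stable month: mean FBG 6.5
        recs += [measurement("P-T1", "FBG", 6.5, day=d) for d in range(5, 30, 5)]
        dp.reevaluate(state, recs, BASE + dt.timedelta(days=30), config, rules)
        assert state.level is dp.ManagementLevel.LEVEL_3_INTENSIVE  # hysteresis holds
        recs += [measurement("P-T1", "FBG", 6.5, day=d) for d in range(35, 60, 5)]
        dp.reevaluate(state, recs, BASE + dt.timedelta(days=60), config, rules)
        assert state.level is dp.ManagementLevel.LEVEL_1_ROUTINE
        assert state.level_history[-1][0] == BASE + dt.timedelta(days=60)

    def test_upgrade_is_immediate(self, profile, rules, config):
        state = _state(profile, rules, config, fbg=6.0)
        assert state.level is dp.ManagementLevel.LEVEL_1_ROUTINE
        recs = list(state.records) + [measurement("P-T1", "FBG", 12.0, day=30)]
        dp.reevaluate(state, recs, BASE + dt.timedelta(days=30), config, rules)
        assert state.level is dp.ManagementLevel.LEVEL_3_INTENSIVE

    def test_no_new_data_leaves_state_unchanged(self, profile, rules, config):
        state = _state(profile, rules, config, fbg=8.0)
        level, history = state.level, list(state.level_history)
        dp.reevaluate(state, [], BASE + dt.timedelta(days=40), config, rules)
        assert state.level == level and state.level_history == history


class TestStep:
    def test_hypoglycemia_raises_warning_and_books_next_day_followup(
        self, profile, rules, config
    ):
        state = _state(profile, rules, config, fbg=8.0)
        day1 = BASE + dt.timedelta(days=1)
        state, events = dp.step(
            state, [measurement("P-T1", "FBG", 2.9, day=1)], [], day1, rules, config
        )
        warnings = [e for e in events if isinstance(e, dp.Warning)]
        assert [w.type for w in warnings] == ["BG_WARNING"]
        assert [e.date for e in state.pending_followups] == [day1 + dt.timedelta(days=1)]
        state, events = dp.step(state, [], [], day1 + dt.timedelta(days=1), rules, config)
        followups = [e for e in events if isinstance(e, FollowUpEvent)]
        assert [f.category for f in followups] == ["abnormal_attention"]
        assert followups[0].warning_type == "BG_WARNING"

    def test_quiet_day_emits_nothing(self, profile, rules, config):
        state = _state(profile, rules, config, fbg=8.0)
        state, events = dp.step(
            state, [measurement("P-T1", "FBG", 8.1, day=1)],
            [dp.TaskRecord("P-T1", "self_monitoring", BASE + dt.timedelta(days=1),
                           True, BASE + dt.timedelta(days=1))],
            BASE + dt.timedelta(days=1), rules, config,
        )
        assert events == []

    def test_repeated_same_date_call_is_idempotent(self, profile, rules, config):
        state = _state(profile, rules, config, fbg=8.0)
        day = BASE + dt.timedelta(days=1)
        recs = [measurement("P-T1", "FBG", 2.9, day=1)]
        state, first = dp.step(state, recs, [], day, rules, config)
        state, second = dp.step(state, recs, [], day, rules, config)
        assert first == second
        assert len(state.pending_followups) == 1  # not double-booked

    def test_backwards_date_is_rejected(self, profile, rules, config):
        state = _state(profile, rules, config, fbg=8.0)
        dp.step(state, [], [], BASE + dt.timedelta(days=5), rules, config)
        with pytest.raises(dp.ReplayError):
            dp.step(state, [], [], BASE + dt.timedelta(days=4), rules, config)

    def test_adherent_in_range_level2_cycle_yields_three_regular_contacts(
        self, profile, rules, config
    ):
        state = _state(profile, rules, config, fbg=8.0)
        assert state.level is dp.ManagementLevel.LEVEL_2_ROUTINE
        events = []
        for d in range(1, 91):
            date = BASE + dt.timedelta(days=d)
            recs = (
                [measurement("P-T1", "FBG", 8.0, day=d),
                 measurement("P-T1", "PBG", 11.0, day=d)]
                if d % 2 == 0
                else []
            )
            tasks = [dp.TaskRecord("P-T1", "self_monitoring", date, True, date)]
            state, day_events = dp.step(state, recs, tasks, date, rules, config)
            events.extend(day_events)
        followups = [e for e in events if isinstance(e, FollowUpEvent)]
        assert [f.category for f in followups] == ["regular"] * 3
        assert [f.date for f in followups] == [
            BASE + dt.timedelta(days=k) for k in (30, 60, 90)
        ]
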