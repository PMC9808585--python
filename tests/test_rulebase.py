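"""Rule loading, forward-chaining inference, explanation and summaries.

The inference fixpoint is cross-checked against an independent brute-force
oracle that enumerates rule-application orders.
"""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diapath as dp
from diapath.rulebase import RULE_MODULES, Atom

# ---------------------------------------------------------------------------
# brute-force closure oracle (independent of the engine's fixpoint loop)
# ---------------------------------------------------------------------------

def _atom_holds(atom: Atom, facts: dict, derived: dict) -> bool:
    if atom.predicate in facts:
        value, present = facts[atom.predicate], True
    elif derived.get(atom.predicate):
        value, present = frozenset(derived[atom.predicate]), True
    else:
        value, present = None, False
    return atom.holds(value, present)


def _apply_in_order(order, facts):
    """Run rules repeatedly in one fixed order until nothing new is derived."""
    derived: dict[str, set] = {}
    for _ in range(100):
        changed = False
        for rule in order:
            if all(_atom_holds(a, facts, derived) for a in rule.conditions):
                for act in rule.actions:
                    if act.value not in derived.setdefault(act.predicate, set()):
                        derived[act.predicate].add(act.value)
                        changed = True
        if not changed:
            break
    return {(p, v) for p, vs in derived.items() for v in vs}


def brute_force_closure(facts: dict, rules) -> set:
    """Closure over every rule-application order (sampled above 5 rules)."""
    if len(rules) <= 5:
        orders = itertools.permutations(rules)
    else:
        rnd = random.Random(0)
        orders = [rnd.sample(list(rules), len(rules)) for _ in range(24)]
    results = {frozenset(_apply_in_order(order, facts)) for order in orders}
    assert len(results) == 1, "closure depended on application order"
    return set(next(iter(results)))


def _multi_rule(rule_id, conditions, actions, priority=0):
    return dp.Rule(
        rule_id=rule_id,
        module="risk_assessment",
        provenance="expert",
        priority=priority,
        conditions=tuple(Atom(*c) for c in conditions),
        actions=tuple(dp.Assertion(p, v) for p, v in actions),
    )


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoading:
    def test_shipped_rulebase_covers_all_ten_modules(self, rules):
        modules = {r.module for r in rules}
        assert modules == set(RULE_MODULES)
        assert {r.provenance for r in rules} <= {"expert", "guideline", "both"}

    def test_duplicate_rule_id_rejected(self):
        spec = [
            {"rule_id": "R1", "module": "risk_assessment", "provenance": "expert",
             "conditions": [{"predicate": "age", "comparator": ">=", "operand": 60}],
             "actions": [{"predicate": "risk_factor", "value": "advanced_age"}]},
        ] * 2
        with pytest.raises(dp.RuleBaseError, match="duplicate"):
            dp.load_rulebase(spec)

    def test_empty_rulebase_is_valid_identity(self):
        assert dp.load_rulebase([]) == []
        result = dp.infer({"latest_FBG": 12.0}, [])
        assert result.assertions == set()

    @pytest.mark.parametrize(
        "field,value,message",
        [
            ("module", "nutrition", "unknown module"),
            ("provenance", "vendor", "unknown provenance"),
        ],
    )
    def test_unknown_enum_values_rejected(self, field, value, message):
        spec = {"rule_id": "R1", "module": "risk_assessment", "provenance": "expert",
                "conditions": [{"predicate": "age", "comparator": ">=", "operand": 60}],
                "actions": [{"predicate": "risk_factor", "value": "advanced_age"}]}
        spec[field] = value
        with pytest.raises(dp.RuleBaseError, match=message):
            dp.load_rulebase([spec])

    def test_unknown_predicate_rejected(self):
        spec = [{"rule_id": "R1", "module": "risk_assessment", "provenance": "expert",
                 "conditions": [{"predicate": "shoe_size", "comparator": ">", "operand": 40}],
                 "actions": [{"predicate": "risk_factor", "value": "x"}]}]
        with pytest.raises(dp.RuleBaseError, match="unknown predicate"):
            dp.load_rulebase(spec)

    def test_actions_cannot_write_input_predicates(self):
        spec = [{"rule_id": "R1", "module": "risk_assessment", "provenance": "expert",
                 "conditions": [{"predicate": "age", "comparator": ">", "operand": 40}],
                 "actions": [{"predicate": "latest_FBG", "value": 5.0}]}]
        with pytest.raises(dp.RuleBaseError, match="derived"):
            dp.load_rulebase(spec)

    def test_negation_only_on_input_predicates(self):
        spec = [{"rule_id": "R1", "module": "risk_assessment", "provenance": "expert",
                 "conditions": [{"predicate": "risk_factor", "comparator": "absent"}],
                 "actions": [{"predicate": "diagnosis_flag", "value": "x"}]}]
        with pytest.raises(dp.RuleBaseError, match="absent"):
            dp.load_rulebase(spec)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

class TestInference:
    def test_high_fasting_glucose_maps_to_intensive_level(self, rules):
        result = dp.infer({"latest_FBG": 12.0}, rules)
        assert result.single("management_level") == 3

    def test_priority_resolves_single_valued_conflict(self):
        base = dp.load_rulebase(
            [
                {"rule_id": "L2", "module": "hierarchical_management", "provenance": "expert",
                 "priority": 20,
                 "conditions": [{"predicate": "latest_FBG", "comparator": ">", "operand": 7.0}],
                 "actions": [{"predicate": "management_level", "value": 2}]},
                {"rule_id": "L3", "module": "hierarchical_management", "provenance": "expert",
                 "priority": 30,
                 "conditions": [{"predicate": "latest_FBG", "comparator": ">", "operand": 11.1}],
                 "actions": [{"predicate": "management_level", "value": 3}]},
            ]
        )
        assert dp.infer({"latest_FBG": 12.0}, base).single("management_level") == 3
        assert dp.infer({"latest_FBG": 8.0}, base).single("management_level") == 2

    def test_fixpoint_matches_bruteforce_on_five_rule_base(self):
        rules = [
            _multi_rule("A", [("latest_FBG", ">", 7.0)], [("risk_factor", "hyperglycemia")]),
            _multi_rule("B", [("has_hypertension", "=", True)], [("risk_factor", "hypertension")]),
            _multi_rule("C", [("risk_factor", "=", "hyperglycemia")], [("diagnosis_flag", "bg_out")]),
            _multi_rule("D", [("diagnosis_flag", "=", "bg_out"),
                              ("risk_factor", "=", "hypertension")],
                        [("warning", "BG_WARNING")]),
            _multi_rule("E", [("age", ">=", 60)], [("risk_factor", "advanced_age")]),
        ]
        facts = {"latest_FBG": 9.0, "has_hypertension": True, "age": 64, "smoker": True}
        expected = brute_force_closure(facts, rules)
        got = {(a.predicate, a.value) for a in dp.infer(facts, rules).assertions}
        assert got == expected
        # hand-derived: the two-step chain through C must reach D
        assert ("warning", "BG_WARNING") in got

    def test_explain_reconstructs_two_step_chain(self):
        rules = [
            _multi_rule("RISK", [("latest_FBG", ">", 7.0)], [("risk_factor", "hyperglycemia")]),
            _multi_rule("FLAG", [("risk_factor", "=", "hyperglycemia")],
                        [("diagnosis_flag", "bg_out")]),
        ]
        result = dp.infer({"latest_FBG": 9.0}, rules)
        chain = dp.explain(dp.Assertion("diagnosis_flag", "bg_out"), result.trace)
        assert [rid for rid, _ in chain] == ["RISK", "FLAG"]
        assert chain[0][1] == {"latest_FBG": 9.0}

    def test_explain_single_step_reads_bound_facts(self, rules):
        result = dp.infer({"latest_FBG": 12.0}, rules)
        chain = dp.explain(dp.Assertion("management_level", 3), result.trace)
        assert chain[-1][0] == "HM-01"
        assert chain[-1][1] == {"latest_FBG": 12.0}

    def test_explain_underived_assertion_errors(self, rules):
        result = dp.infer({"latest_FBG": 6.0, "latest_PBG": 8.0}, rules)
        with pytest.raises(KeyError):
            dp.explain(dp.Assertion("management_level", 3), result.trace)

    def test_rule_order_in_file_is_irrelevant(self, rules):
        facts = {"latest_FBG": 12.5, "latest_PBG": 11.0, "has_hypertension": True,
                 "age": 66, "compliance_rate_7d": 0.3}
        baseline = dp.infer(facts, rules).assertions
        for seed in range(3):
            shuffled = list(rules)
            random.Random(seed).shuffle(shuffled)
            assert dp.infer(facts, shuffled).assertions == baseline


# conflict-free random bases: inputs -> multi-valued derived chains
_FACTS = st.fixed_dictionaries(
    {},
    optional={
        "latest_FBG": st.sampled_from([5.0, 8.0, 12.0]),
        "age": st.sampled_from([40, 65]),
        "has_hypertension": st.booleans(),
    },
)
_INPUT_ATOM = st.one_of(
    st.tuples(st.just("latest_FBG"), st.sampled_from([">", "<="]), st.sampled_from([6.0, 10.0])),
    st.tuples(st.just("age"), st.sampled_from([">=", "<"]), st.just(60)),
    st.tuples(st.just("has_hypertension"), st.just("="), st.booleans()),
)
_DERIVED_VALUES = ["r0", "r1", "r2", "r3"]
_DERIVED_ATOM = st.tuples(
    st.just("risk_factor"), st.just("="), st.sampled_from(_DERIVED_VALUES)
)
_ACTION = st.one_of(
    st.tuples(st.just("risk_factor"), st.sampled_from(_DERIVED_VALUES)),
    st.tuples(st.just("diagnosis_flag"), st.sampled_from(["d0", "d1"])),
)
_RULES = st.lists(
    st.tuples(
        st.lists(st.one_of(_INPUT_ATOM, _DERIVED_ATOM), min_size=1, max_size=2),
        st.lists(_ACTION, min_size=1, max_size=2),
    ),
    min_size=0,
    max_size=8,
)


class TestClosureProperties:
    @settings(deadline=None, max_examples=60)
    @given(facts=_FACTS, specs=_RULES)
    def test_fixpoint_equals_bruteforce_closure(self, facts, specs):
        rules = [
            _multi_rule(f"G{i}", conds, acts) for i, (conds, acts) in enumerate(specs)
        ]
        expected = brute_force_closure(facts, rules)
        got = {(a.predicate, a.value) for a in dp.infer(facts, rules).assertions}
        assert got == expected

    @settings(deadline=None, max_examples=60)
    @given(facts=_FACTS, specs=_RULES)
    def test_adding_a_fact_is_monotone(self, facts, specs):
        rules = [
            _multi_rule(f"G{i}", conds, acts) for i, (conds, acts) in enumerate(specs)
        ]
        base = dp.infer(facts, rules).assertions
        extended = dict(facts)
        extended.setdefault("smoker", True)
        assert dp.infer(extended, rules).assertions >= base


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

class TestSummary:
    def test_shipped_base_counts_sum_and_cover_modules(self, rules):
        s = dp.rulebase_summary(rules)
        assert s.total == len(rules)
        per_module = s.counts.drop(index="total")["total"]
        assert (per_module > 0).all()

    def test_empty_base_gives_zero_table(self):
        s = dp.rulebase_summary([])
        assert s.total == 0
        assert set(s.provenance_shares.values()) == {0.0}

    def test_provenance_shares_from_printed_split(self):
        # 192 rules, 44 expert / 83 guideline / 65 both -> 22.9 / 43.2 / 33.9 %
        def rule(i, prov):
            return dp.Rule(
                rule_id=f"R{i:03d}",
                module=RULE_MODULES[i % 10],
                provenance=prov,
                conditions=(Atom("age", ">", 0),),
                actions=(dp.Assertion("risk_factor", f"v{i}"),),
            )

        rules = (
            [rule(i, "expert") for i in range(44)]
            + [rule(44 + i, "guideline") for i in range(83)]
            + [rule(127 + i, "both") for i in range(65)]
        )
        s = dp.rulebase_summary(rules)
        assert s.total == 192
        assert s.provenance_shares == {"expert": 22.9, "guideline": 43.2, "both": 33.9}

    def test_shares_are_permutation_invariant(self, rules):
        shuffled = list(rules)
        random.Random(7).shuffle(shuffled)
        assert (
            dp.rulebase_summary(shuffled).provenance_shares
            == dp.rulebase_summary(rules).provenance_shares
        )
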