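"""Declarative condition→action rules and forward-chaining inference.

The pathway's medical knowledge is expressed as flat condition→action rules
over the patient fact base — the executable analogue of the SWRL-style rules
a care-pathway ontology would carry.  Rules are grouped into ten modules
(diagnosis patterns, risk assessment, control objectives, hierarchical
management, self-monitoring, regular follow-up, abnormal attention,
medication guidance, lifestyle guidance, compliance management) and each is
provenance-labelled as derived from clinical expert experience, from medical
guidelines, or both.

Inference is monotone forward chaining to a fixpoint: rules only ever assert
derived facts, never retract.  Predicates asserted by rules are *derived*
and disjoint from the input predicates extracted from records.  Derived
predicates declared single-valued (e.g. ``management_level``) resolve
conflicting assertions by rule priority, then lexicographic rule id;
multi-valued ones (e.g. ``plan_item``) accumulate.  Negated conditions
(``absent``) are only legal on input predicates, which keeps the closure
order-independent and finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .domain_model import FactBase

MAX_ITERATIONS = 1000

RULE_MODULES = (
    "diagnosis_patterns",
    "risk_assessment",
    "control_objectives",
    "hierarchical_management",
    "self_monitoring",
    "regular_follow_up",
    "abnormal_attention",
    "medication_guidance",
    "lifestyle_guidance",
    "compliance_management",
)

PROVENANCES = ("expert", "guideline", "both")

#: predicates extracted from patient records/profile (module domain_model)
INPUT_PREDICATES = frozenset(
    {
        "latest_FBG",
        "latest_PBG",
        "latest_SBP",
        "latest_DBP",
        "latest_HR",
        "latest_WEIGHT",
        "latest_SYMPTOM",
        "mean_FBG_30d",
        "mean_PBG_30d",
        "mean_SBP_30d",
        "mean_DBP_30d",
        "has_hypertension",
        "age",
        "sex",
        "bmi",
        "smoker",
        "compliance_rate_7d",
        "days_since_last_followup",
        "symptom_present",
        "symptom_severity",
    }
)

#: derived predicates that hold exactly one value (priority-resolved)
SINGLE_VALUED_DERIVED = frozenset(
    {
        "management_level",
        "followup_interval_days",
        "risk_category",
        "target_fbg",
        "target_pbg",
        "target_sbp",
        "target_dbp",
        "compliance_followup_due",
    }
)

#: derived predicates that accumulate a set of values
MULTI_VALUED_DERIVED = frozenset(
    {"warning", "plan_item", "risk_factor", "diagnosis_flag"}
)

DERIVED_PREDICATES = SINGLE_VALUED_DERIVED | MULTI_VALUED_DERIVED

_COMPARATOR_ALIASES = {
    "<=": "<=",
    "≤": "<=",
    ">=": ">=",
    "≥": ">=",
    "<": "<",
    ">": ">",
    "=": "=",
    "==": "=",
    "in": "in",
    "∈": "in",
    "present": "present",
    "absent": "absent",
}


class RuleBaseError(ValueError):
    """Malformed rule file or rule-base defect detected at run time."""


def _freeze(value: Any) -> Any:
    """Canonical hashable form of an action value (dicts → sorted item tuples)."""
    if isinstance(value, dict):
        return tuple(sorted((k, _freeze(v)) for k, v in value.items()))
    if isinstance(value, (list, tuple, set)):
        return tuple(_freeze(v) for v in value)
    return value


def thaw(value: Any) -> Any:
    """Inverse of :func:`_freeze` for tuple-encoded mappings."""
    if (
        isinstance(value, tuple)
        and value
        and all(isinstance(i, tuple) and len(i) == 2 and isinstance(i[0], str) for i in value)
    ):
        return {k: thaw(v) for k, v in value}
    if isinstance(value, tuple):
        return [thaw(v) for v in value]
    return value


@dataclass(frozen=True)
class Atom:
    """One condition: ``predicate comparator operand``."""

    predicate: str
    comparator: str
    operand: Any = None

    def __post_init__(self) -> None:
        comp = _COMPARATOR_ALIASES.get(str(self.comparator))
        if comp is None:
            raise RuleBaseError(f"unknown comparator {self.comparator!r}")
        object.__setattr__(self, "comparator", comp)
        object.__setattr__(self, "operand", _freeze(self.operand))
        if comp in ("<", "<=", ">", ">="):
            if not isinstance(self.operand, (int, float)) or isinstance(self.operand, bool):
                raise RuleBaseError(
                    f"{self.predicate}: numeric comparator needs a numeric operand"
                )
        if comp == "in" and not isinstance(self.operand, tuple):
            raise RuleBaseError(f"{self.predicate}: 'in' needs a set/list operand")

    def holds(self, value: Any, present: bool) -> bool:
        if self.comparator == "present":
            return present
        if self.comparator == "absent":
            return not present
        if not present:
            return False
        # multi-valued predicates satisfy an atom if any held value does
        values = value if isinstance(value, frozenset) else (value,)
        for v in values:
            if self._holds_one(v):
                return True
        return False

    def _holds_one(self, v: Any) -> bool:
        c, op = self.comparator, self.operand
        if c == "=":
            return v == op
        if c == "in":
            return v in op
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            return False
        if c == "<":
            return v < op
        if c == "<=":
            return v <= op
        if c == ">":
            return v > op
        return v >= op  # ">="


@dataclass(frozen=True)
class Assertion:
    """One derived fact produced by a rule firing."""

    predicate: str
    value: Any

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _freeze(self.value))

    def value_as_dict(self) -> Any:
        return thaw(self.value)


@dataclass(frozen=True)
class Rule:
    rule_id: str
    module: str
    provenance: str
    conditions: tuple[Atom, ...]
    actions: tuple[Assertion, ...]
    priority: int = 0

    def __post_init__(self) -> None:
        if self.module not in RULE_MODULES:
            raise RuleBaseError(f"{self.rule_id}: unknown module {self.module!r}")
        if self.provenance not in PROVENANCES:
            raise RuleBaseError(f"{self.rule_id}: unknown provenance {self.provenance!r}")
        if not self.conditions:
            raise RuleBaseError(f"{self.rule_id}: conditions must be nonempty")
        if not self.actions:
            raise RuleBaseError(f"{self.rule_id}: actions must be nonempty")
        for atom in self.conditions:
            if atom.predicate not in INPUT_PREDICATES | DERIVED_PREDICATES:
                raise RuleBaseError(
                    f"{self.rule_id}: unknown predicate {atom.predicate!r}"
                )
            if atom.comparator == "absent" and atom.predicate not in INPUT_PREDICATES:
                raise RuleBaseError(
                    f"{self.rule_id}: 'absent' only allowed on input predicates"
                )
        for act in self.actions:
            if act.predicate not in DERIVED_PREDICATES:
                raise RuleBaseError(
                    f"{self.rule_id}: actions must assert derived predicates, "
                    f"got {act.predicate!r}"
                )

    @property
    def sort_key(self) -> tuple[int, str]:
        return (-self.priority, self.rule_id)


@dataclass(frozen=True)
class Firing:
    """Trace entry: a rule whose conditions held, with the bound facts."""

    rule_id: str
    bindings: tuple[tuple[str, Any], ...]
    assertions: tuple[Assertion, ...]


@dataclass
class InferenceResult:
    assertions: set[Assertion] = field(default_factory=set)
    trace: list[Firing] = field(default_factory=list)

    def values(self, predicate: str) -> list[Any]:
        return [a.value_as_dict() for a in sorted(
            (a for a in self.assertions if a.predicate == predicate),
            key=lambda a: repr(a.value),
        )]

    def single(self, predicate: str, default: Any = None) -> Any:
        vals = [a.value for a in self.assertions if a.predicate == predicate]
        if not vals:
            return default
        if len(vals) > 1:
            raise RuleBaseError(f"{predicate}: multiple resolved values {vals}")
        return thaw(vals[0])


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _rule_from_dict(d: Mapping[str, Any]) -> Rule:
    return Rule(
        rule_id=str(d["rule_id"]),
        module=str(d["module"]),
        provenance=str(d["provenance"]),
        priority=int(d.get("priority", 0)),
        conditions=tuple(
            Atom(
                predicate=str(c["predicate"]),
                comparator=str(c["comparator"]),
                operand=c.get("operand"),
            )
            for c in d["conditions"]
        ),
        actions=tuple(
            Assertion(predicate=str(a["predicate"]), value=a.get("value"))
            for a in d["actions"]
        ),
    )


def load_rulebase(source: str | Path | Sequence[Mapping[str, Any]]) -> list[Rule]:
    """Load and validate a rule file (JSON array of rule objects).

    Returns rules in stable order (priority descending, then rule id).
    Raises :class:`RuleBaseError` on duplicate rule ids, unknown modules,
    provenances, comparators or predicates.
    """
    if isinstance(source, (str, Path)):
        data = json.loads(Path(source).read_text())
    else:
        data = list(source)
    if not isinstance(data, list):
        raise RuleBaseError("rule file must be a JSON array of rule objects")
    rules = [_rule_from_dict(d) for d in data]
    seen: set[str] = set()
    for r in rules:
        if r.rule_id in seen:
            raise RuleBaseError(f"duplicate rule_id {r.rule_id!r}")
        seen.add(r.rule_id)
    rules.sort(key=lambda r: r.sort_key)
    return rules


def load_default_rules() -> list[Rule]:
    """The rule base shipped with the package (all ten modules represented)."""
    with resources.files("diapath.data").joinpath("default_rules.json").open() as fh:
        return load_rulebase(json.load(fh))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _fact_view(
    inputs: Mapping[str, Any],
    single: Mapping[str, tuple[tuple[int, str], Any]],
    multi: Mapping[str, set[Any]],
):
    def lookup(predicate: str) -> tuple[Any, bool]:
        if predicate in inputs:
            return inputs[predicate], True
        if predicate in single:
            return single[predicate][1], True
        if predicate in multi and multi[predicate]:
            return frozenset(multi[predicate]), True
        return None, False

    return lookup


def infer(
    facts: FactBase | Mapping[str, Any],
    rules: Sequence[Rule],
    seed_assertions: Iterable[Assertion] = (),
) -> InferenceResult:
    """Forward-chain ``rules`` over ``facts`` to a fixpoint.

    Monotone: derived facts are only added.  Conflicting assertions on a
    single-valued predicate resolve to the highest-priority rule (ties by
    lexicographic rule id).  The trace records every rule firing with the
    facts its conditions bound.  ``seed_assertions`` pre-populates derived
    facts (used e.g. to build plans for an already-assigned level).
    """
    inputs = dict(facts.facts if isinstance(facts, FactBase) else facts)
    bad = set(inputs) - INPUT_PREDICATES
    if bad:
        raise RuleBaseError(f"unknown input predicates: {sorted(bad)}")

    # setter precedence key: lower sorts first = stronger claim
    top_key = (-(10**9), "")
    single: dict[str, tuple[tuple[int, str], Any]] = {}
    multi: dict[str, set[Any]] = {}
    for a in seed_assertions:
        if a.predicate in SINGLE_VALUED_DERIVED:
            single[a.predicate] = (top_key, a.value)
        else:
            multi.setdefault(a.predicate, set()).add(a.value)

    ordered = sorted(rules, key=lambda r: r.sort_key)
    lookup = _fact_view(inputs, single, multi)
    fired: set[str] = set()
    trace: list[Firing] = []

    for iteration in range(MAX_ITERATIONS + 1):
        if iteration == MAX_ITERATIONS:
            raise RuleBaseError("inference did not reach a fixpoint (malformed rule base)")
        changed = False
        for rule in ordered:
            bindings = []
            ok = True
            for atom in rule.conditions:
                value, present = lookup(atom.predicate)
                if not atom.holds(value, present):
                    ok = False
                    break
                bindings.append((atom.predicate, value))
            if not ok:
                continue
            if rule.rule_id not in fired:
                fired.add(rule.rule_id)
                trace.append(
                    Firing(rule.rule_id, tuple(bindings), tuple(rule.actions))
                )
            for act in rule.actions:
                if act.predicate in SINGLE_VALUED_DERIVED:
                    key = rule.sort_key
                    held = single.get(act.predicate)
                    if held is None or (key < held[0] and act.value != held[1]):
                        single[act.predicate] = (key, act.value)
                        changed = True
                else:
                    bucket = multi.setdefault(act.predicate, set())
                    if act.value not in bucket:
                        bucket.add(act.value)
                        changed = True
        if not changed:
            break

    assertions = {Assertion(p, v) for p, (_, v) in single.items()}
    assertions |= {Assertion(p, v) for p, vs in multi.items() for v in vs}
    return InferenceResult(assertions=assertions, trace=trace)


def explain(
    assertion: Assertion, trace: Sequence[Firing]
) -> list[tuple[str, dict[str, Any]]]:
    """Minimal derivation chain for ``assertion``, support rules first.

    Returns ``[(rule_id, matched_facts), ...]`` ending with the rule that
    asserted ``assertion``.  Raises ``KeyError`` if the assertion does not
    appear in the trace.
    """
    producer = None
    for firing in trace:
        for act in firing.assertions:
            if act.predicate == assertion.predicate and act.value == _freeze(
                assertion.value
            ):
                producer = firing
                break
        if producer:
            break
    if producer is None:
        raise KeyError(f"assertion {assertion} was not derived")

    chain: list[tuple[str, dict[str, Any]]] = []
    seen: set[str] = set()

    def expand(firing: Firing) -> None:
        if firing.rule_id in seen:
            return
        seen.add(firing.rule_id)
        for pred, bound in firing.bindings:
            if pred in DERIVED_PREDICATES:
                # find the firing that supplied this derived fact
                values = bound if isinstance(bound, frozenset) else {bound}
                for support in trace:
                    if support is firing:
                        continue
                    if any(
                        a.predicate == pred and a.value in values
                        for a in support.assertions
                    ):
                        expand(support)
                        break
        chain.append((firing.rule_id, {p: thaw(v) for p, v in firing.bindings}))

    expand(producer)
    return chain


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def _round_half_up(x: float, ndigits: int = 1) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RulebaseSummary:
    counts: pd.DataFrame  #: modules × provenance counts, with margin totals
    provenance_shares: dict[str, float]  #: % of all rules per provenance, 1 dp

    @property
    def total(self) -> int:
        return int(self.counts.loc["total", "total"])


def rulebase_summary(rules: Sequence[Rule]) -> RulebaseSummary:
    """Counts by module × provenance, plus provenance column shares in %."""
    counts = pd.DataFrame(0, index=list(RULE_MODULES), columns=list(PROVENANCES))
    for r in rules:
        counts.loc[r.module, r.provenance] += 1
    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)
    total = int(counts.loc["total", "total"])
    shares = {
        p: _round_half_up(100.0 * counts.loc["total", p] / total, 1) if total else 0.0
        for p in PROVENANCES
    }
    return RulebaseSummary(counts=counts, provenance_shares=shares)
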