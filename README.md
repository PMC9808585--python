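# diapath

A rule-driven, closed-loop decision-support engine for managing type 2
diabetes mellitus (T2DM) cohorts over telehealth, with a synthetic-cohort
simulator and the retrospective analytics to evaluate a 90-day management
cycle.

## The problem and who this is for

Chronic-disease management pathways formalize *who does what, when*: a
diabetic patient self-monitors according to a personal plan, while the
care provider follows up on a cadence driven by how well the patient's
glucose is controlled and intervenes immediately when a reading is
abnormal or adherence collapses. `diapath` is for researchers and
engineers studying such pathway models: it makes the whole loop —
stratification rules, scheduling, alerting, compliance management, care
plans — executable, replayable and measurable on synthetic electronic
health record streams.

## The model

Nine pathway tasks in three sets drive the loop:

* **regular management** — risk assessment, hierarchical management,
  self-monitoring, regular follow-up;
* **pathway variation** — abnormal attention and compliance management;
* **self-management support** — medication guidance, lifestyle guidance,
  health education.

**Hierarchical management.** With fasting blood glucose FBG (mmol/L) and
2-h postprandial glucose PBG, a patient's management level is

* level 3 (intensive) iff FBG > 11.1,
* level 1 (routine) iff FBG ≤ 7.0 and PBG ≤ 10.0 (stable),
* level 2 (routine) otherwise (above target but not intensive).

Regular follow-ups occur every 30 days at levels 2–3 (so exactly 3 visits
per 90-day cycle) and every 90 days at level 1. Condition is re-evaluated
every 30 days on trailing-30-day means: upgrades are immediate, downgrades
need two consecutive stable reviews.

**Rules.** Clinical knowledge is a declarative JSON rule base
(condition → action atoms over a per-patient fact base), organized into
ten modules with expert/guideline/both provenance labels, executed by a
monotone forward-chaining engine with full explanation traces
(`explain()` returns the derivation chain of any conclusion).

**Variation.** Warning bounds (configurable): any BG < 3.9 or ≥ 16.7,
FBG ≥ 13.9; SBP ≥ 160 or < 90, DBP ≥ 100 (mmHg); HR < 50 or > 120 bpm;
symptom severity ≥ 2. A warning books a physician contact the next day; a
7-day task-completion rate below 0.5 books a compliance contact (at most
one per window).

**Simulator.** The cohort generator reproduces a 272-patient study mix
(42.6% comorbid hypertension, 65.1% abnormal baseline glucose, 69.8%
abnormal baseline pressure among hypertensives, mean age 58.24) and
intervention-responsive trajectories: each completed follow-up lowers the
patient's latent means (defaults −0.8 FBG, −1.0 PBG mmol/L, −6/−5 mmHg)
from the next 30-day month onward.

## Worked example

```python
import diapath as dp

rules = dp.load_default_rules()
cohort = dp.simulate_cohort(dp.CohortConfig(seed=17))      # 272 patients, 90 days
events, states = dp.run_closed_loop(cohort)

s = dp.summarize_followups(events)
print(s.counts, s.shares)
tr = dp.monthly_trend(cohort.measurements, "FBG")
print({k: round(v, 2) for k, v in tr.patient_means.items()}, round(tr.delta, 2))
```

prints

```
{'regular': 655, 'abnormal_attention': 457, 'compliance': 225} {'regular': 49.0, 'abnormal_attention': 34.2, 'compliance': 16.8}
{1: 8.35, 2: 6.87, 3: 6.12} 2.24
```

i.e. physicians made 1337 contacts over the cycle — about half on the
regular schedule, a third triggered by abnormal readings, the rest by low
compliance — and the cohort's monthly mean fasting glucose fell from 8.35
to 6.12 mmol/L (month 1 − month 3 = 2.24 mmol/L, paired t test on
per-patient monthly means). Patients who received variation-triggered
contacts decline more than never-intervened patients, the qualitative
signature of active intervention.

A `diapath` console script wraps the same functions
(`simulate`, `run`, `plan`, `analyze`, `validate-rules`); see
`diapath --help`.

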