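# Methods

## The pathway model

`diapath` implements a closed-loop chronic-care pathway for type 2
diabetes as three cooperating layers:

1. **Fact extraction** (`domain_model`). At any decision date a patient is
   summarized by a flat fact base: the latest value per measurement kind,
   trailing-30-day means of glucose and blood pressure, comorbidity and
   demographic flags, a 7-day task-completion rate and days since the last
   physician contact. Facts only ever use records time-stamped at or
   before the decision date (no lookahead), and extraction is
   deterministic and order-insensitive (records are sorted by timestamp;
   equal-timestamp duplicates keep the last-read value with a warning).
   Scheduling is day-granular; a "month" is 30 days and a management
   cycle 90 days, which makes every schedule deterministic.

2. **Declarative rules** (`rulebase`). Medical knowledge lives in a JSON
   rule file, not in code: condition → action rules over the fact base,
   grouped into ten modules (diagnosis patterns, risk assessment, control
   objectives, hierarchical management, self-monitoring, regular
   follow-up, abnormal attention, medication guidance, lifestyle
   guidance, compliance management), each labelled with its provenance
   (clinical expert experience, medical guidelines, or both). Inference
   is monotone forward chaining to a fixpoint. Design choices that keep
   the closure well-behaved:
   * actions may only assert *derived* predicates, disjoint from the
     input predicates — rules never retract, so the closure is finite and
     monotone;
   * negated conditions (`absent`) are legal only on input predicates,
     which keeps the fixpoint independent of application order;
   * derived predicates declared single-valued (`management_level`,
     `followup_interval_days`, …) resolve competing assertions by rule
     priority, then lexicographic rule id — so permuting the rule file
     never changes the outcome; multi-valued predicates (`warning`,
     `plan_item`, …) accumulate;
   * numeric comparisons are exact on the values as read; thresholds are
     data, not code.
   Every firing is traced, and `explain()` reconstructs the minimal
   derivation chain of any conclusion — the transparency a physician-facing
   system needs.

   The shipped default rule base (44 rules covering all ten modules) is a
   representative authored set: the taxonomy and the stratification
   thresholds are fixed by the pathway definition, the individual rule
   texts are this package's own formulation.

3. **The state machine** (`pathway_engine`, `variation`, `care_plans`).
   Enrollment runs risk assessment, assigns a level and schedules regular
   follow-ups. The daily `step()` completes booked contacts, emits due
   regular follow-ups, scans the day's records for warnings, checks
   compliance, and re-evaluates the condition every 30 days. It is
   idempotent per date and rejects backwards time, so an event log can be
   replayed byte-identically.

## Key parameters (units, defaults, rationale)

| parameter | default | why |
|---|---|---|
| intensive FBG bound | > 11.1 mmol/L (strict) | the pathway's stated intensive-management criterion |
| control targets | FBG ≤ 7.0, PBG ≤ 10.0 mmol/L | the Chinese T2DM guideline control targets; "stable" vs "unsatisfactory" glucose is not otherwise quantified |
| follow-up intervals | 90/30/30 d for levels 1/2/3 | guidelines mandate monthly contact only for substandard glucose; stable patients are seen once per cycle |
| re-evaluation | every 30 d on 30-day means | means smooth single-reading noise; the latest fasting reading above 11.1 still forces level 3 immediately (safety) |
| downgrade hysteresis | 2 consecutive stable reviews | prevents level oscillation; upgrades are immediate |
| warning bounds | BG < 3.9 / ≥ 16.7, FBG ≥ 13.9; SBP ≥ 160 / < 90, DBP ≥ 100; HR < 50 / > 120; symptom ≥ 2 | hypoglycemia / severe-hyperglycemia and urgent-blood-pressure conventions of the guidelines the pathway draws on; all configurable |
| compliance | rate < 0.5 over 7 d | unquantified in the pathway source; chosen so compliance contacts are of the same order as abnormal-attention contacts in the default simulator |
| abnormal contact debounce | ≥ 7 d between abnormal-attention contacts | a booked contact covers repeated warnings in the window; daily-monitored uncontrolled hypertensives would otherwise accrue ~30 contacts/month, far beyond any observed physician workload |
| monitoring frequency | 1/3/7 days per week for levels 1/2/3, BP daily iff hypertensive | guideline-informed defaults, shipped inside the self-monitoring rules; `EngineConfig.monitoring_days_per_week` overrides |

Risk assessment has no published formula at this granularity; it is a
configurable risk-factor count (hypertension, age ≥ 60, BMI ≥ 28,
smoking) feeding rule conditions only — explicitly a design choice of
this package, not pathway content.

## The synthetic cohort

`cohort_simulator` emulates the study conditions every other module is
tested under: n = 272 patients followed 90 days, 42.6% with comorbid
hypertension, 65.1% abnormal baseline glucose, 69.8% abnormal baseline
pressure among hypertensives, 54% male, age mean 58.24 (SD 9.81), 2.5%
adolescents, 0.7% with disabilities. Adult ages are drawn so the cohort
mean (including adolescents at 13–17) matches the configured mean; the
cohort age SD is therefore slightly larger than the adult SD.

Each patient owns an independent random stream keyed by
`(seed, patient_index)`, so growing the cohort never perturbs existing
patients. Baselines are normal/abnormal mixtures (e.g. abnormal fasting
glucose latent mean 9.3, truncated to 7.2–12.5 mmol/L — severe outliers
are excluded from managed cohorts; abnormal systolic latent 152,
truncated 142–175 mmHg); daily readings add i.i.d. noise.

**Intervention response.** Latent means are piecewise-constant per 30-day
month: every follow-up the physician completes in month *m* (any
category) lowers the latent means from month *m*+1 by the configured
effects (−0.8 FBG, −1.0 PBG mmol/L; −6/−5 mmHg per contact), floored at
physiologic values (4.5/6.5 mmol/L, 112/68 mmHg). This makes the
generative model exactly linear for non-floored patients — the
per-patient month-1 − month-3 decline equals *effect* × *contacts
received in months 1–2* plus measurement noise — which is what makes the
effect-recovery regression in the test suite well-posed: it excludes
floor-censored patients (identifiable from the recorded latent
baselines) and recovers the generative effect within 2 standard errors
of the multi-seed mean. Effect defaults are tuned to the order of
magnitude of reported T2DM telehealth improvements, not claimed
reproductions of any particular cohort's deltas.

Adherence is a daily task-completion probability (default 0.7), boosted
by +0.2 (capped at 0.95) after each compliance contact. The generator
co-runs the real pathway engine day by day, so monitoring cadence follows
the patient's *current* plan and engine-emitted contacts feed back into
the trajectories; because the engine is deterministic in its inputs,
replaying the generated records reproduces the generation-time event log
exactly.

**What passing tests do not show.** The simulator has no dropout, no
pharmacokinetics, no weekday or seasonal structure, a fixed enrollment
date, and plan-driven (not behavioural) measurement cadence. Directional
results on it — intervened patients decline more than never-intervened —
validate the machinery, not any clinical effect size in real cohorts.

## Analytics conventions

* Percentages round half-up to 1 decimal, means to 2 decimals.
* Months bin days 1–30 / 31–60 / 61–90 since enrollment; day-0 baseline
  records fall in month 1.
* Monthly trends are computed two ways — mean of per-patient monthly
  means (primary, and the basis of the paired two-tailed t test on
  patients present in both months) and plain per-reading means — since
  either convention is defensible.
* Intervention level: more than 3 contacts = high, exactly 3 = medium,
  fewer = low; implemented as the definition (a medium-level patient
  mean is exactly 3.0 by construction).
* Contingency comparisons use Pearson chi-square without continuity
  correction; degenerate tables (fewer than 2×2, zero margins) are
  rejected rather than patched.

## Numerical and degenerate-input choices

* Equal-priority conflicting assertions resolve by lexicographic rule id
  (stable, file-order independent).
* No glycemic facts at all ⇒ level 2 with a logged insufficient-data
  flag; re-evaluation without data leaves the level unchanged.
* An empty compliance window counts as fully compliant (rate 1.0).
* A fixpoint not reached within 1000 sweeps raises a malformed-rule-base
  error (unreachable for valid monotone bases).
* Trajectory noise SDs may be zero so that noise-free null cohorts are
  expressible.

## Known limitations

* Rule conditions are conjunctions of ground atoms — no variables, no
  aggregation inside rules (windowed means are precomputed facts).
* Warning-triggered contacts are attributed to one lead warning type per
  day; regular and abnormal contacts are never merged.
* Medication guidance is class-level only; no dosing, titration or
  interaction checking. Health-education content is a static topic list
  expressed as rules.
* Problem sizes in the test suite (272 patients × 90 days × 20 seed
  replicates for the stochastic properties) are the package's chosen
  study scale; single runs complete in seconds.
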