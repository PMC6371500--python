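# Methods

## Screening model

The unit of screening is the *patient-day*: one structured snapshot of a
patient's EHR state (demographics, active medication orders, laboratory
results, clinical parameters, CDSS drug–drug-interaction override events)
evaluated once a day at a fixed screening instant. The instant defaults to
12:00 noon — a midnight run could not see same-day morning laboratory
results — and is a module constant (`cma.model.SCREENING_TIME`).

Only non-critically-ill inpatients and day-care admissions are screened. ICU
and discharged snapshots are accepted at ingestion but skipped with a logged
message, reflecting the separation of ICU prescribing into a different
system in the service this package models.

A rule is a **conjunction** of criteria; there is no OR within a rule. A
clinical disjunction is expressed as separate rules sharing an advice
template. This keeps each rule auditable: the evidence map attached to an
alert has exactly one entry per criterion, and removing a criterion can only
widen the alerted population (a property the test suite checks).

### Value semantics

- *Most recent value wins*: each threshold criterion uses the latest
  observation at or before the screening instant, within a staleness window.
  Defaults: 72 h for potassium, INR, neutrophil count and QTc; 7 days for
  creatinine and measured clearance. Observations outside the window make
  the criterion silently false (no alert on stale data), a deliberate
  specificity choice.
- *Strict comparators*: all configured thresholds use the comparator exactly
  as written; a value at threshold does not fire. The one deliberate
  exception is the dose-restriction criterion, where "high dose meropenem
  (2 g q8h)" means *at or above* 2 g with an interval *at or below* 8 h, so
  dose uses ≥ and the interval ≤.
- *Half-open order activity*: an order is active on [start, stop), so a drug
  stopped at the screening instant no longer counts — switch days are not
  double-counted.
- *Renal function*: Cockcroft–Gault on actual body weight, refused below 18
  years; a measured/registered clearance takes precedence whenever it is at
  least as recent as the creatinine it would replace.
- *QTc thresholds* are sex-specific (450 ms male / 470 ms female, the
  standard cardiology convention); with unknown sex the stricter threshold
  is used and a warning logged.
- Units are normalised at ingestion to one canonical unit per analyte
  (creatinine mg/dL with µmol/L accepted at ÷88.4, potassium mmol/L,
  INR dimensionless, ANC 10⁹/L, CrCl mL/min); normalisation is idempotent.
- A restricted-indication rule fires when the order's indication is absent
  as well as when it is non-qualifying: an unverifiable indication is a
  reviewable finding, and the pharmacist triage step is the intended filter
  for the resulting false positives.

### Drug coding

Drug classes are encoded as ATC prefix sets plus explicit codes, shipped in
the rule-set YAML. ATC is the standard hospital-formulary classification;
encoding classes this way keeps rule files portable across sites. No
terminology-server lookup is performed. The shipped rule set contains 17
exemplar rules across all five pharmacotherapeutic categories (and all six
biochemical subcategories); it is a representative, extensible subset, not a
complete production catalogue.

## Worklist and triage

Alerts from the four reviewable categories are grouped (category, rule,
patient) on a daily worklist. Sequential-therapy detections never enter it:
they become automatic electronic notes directly.

*Duplicate suppression*: an alert is suppressed when a prior alert within a
7-day horizon exists for the same (patient, rule, triggering drug set) with
identical evidence after unit normalization; any change in any criterion's
observed value makes the alert reappear as new. Equality is exact (full
precision) — "relevant change" is not quantified, so the conservative
reading is that every change is relevant.

*Flowcharts* are data, not code: per-rule decision trees of yes/no questions
over the alert evidence and the current snapshot, each path ending in a
disposition leaf (no action / note / note + phone). Rules without an
explicit flowchart get the default tree — criteria still met? triggering
drug still active? — ending in the rule's escalation channel. A question
that cannot be answered (e.g. the snapshot is unavailable at triage time)
routes to the node's configured conservative branch, defaulting to "yes"
(act rather than dismiss). The human reviewer is modelled as a pluggable
decision source that may override the flowchart's proposal; automatic triage
simply accepts it, which makes the workflow fully deterministic for testing.

## Acceptance classification

An action is *accepted* when a qualifying event occurs within 72 h
(inclusive) after it: a prescription stop, a dose correction, another
documented modification, or a follow-up measurement of the monitored
parameter. Classification order: duplicate exclusion first; then a
discharge/transfer occurring before any qualifying event makes the action
unverifiable (excluded); otherwise the first qualifying event in the window
sets the accepted subtype; otherwise not accepted. Rates are
accepted / (sampled − excluded); a stratum whose actions are all excluded
has an undefined rate, never 0%.

### Percentage rendering

Reported percentages use two-stage half-up rounding: the raw fraction is
rounded half-up to one decimal, and integer-precision figures are rounded
half-up again from that one-decimal value (6.455% → 6.5% → 7%,
8.49% → 8.5% → 9%). This is the convention under which every percentage in
the shipped reference count tables is reproduced exactly; reports also carry
the raw counts so no information is lost to formatting. Auto-precision
rendering keeps one decimal below 2% and an integer otherwise, matching how
small action rates are usually quoted.

## Interrater reliability

Cohen's κ = (p₀ − pₑ)/(1 − pₑ) with chance agreement pₑ from the two raters'
marginal label frequencies. Degenerate case: two identical constant raters
have pₑ = 1; the implementation defines κ = 1 there (perfect agreement) with
a logged note rather than 0/0. For more than two raters the unweighted mean
of pairwise κ is reported. The implementation is cross-checked in the test
suite against scikit-learn's independent computation and a hand-worked 2×2
table (cells 20/5/10/15 → κ = 0.4 exactly).

## Synthetic data

The generator emulates a daily census with *planted* rule triggers: for each
rule independently, a patient-day carries the full trigger conjunction with
the configured prevalence (default 0.02) and a near-miss — all conjuncts
satisfied except one broken conjunct chosen uniformly — with the configured
near-miss fraction (default 0.02). Broken threshold conjuncts sit exactly at
the threshold, which doubles as a boundary-condition probe. Baseline
physiology for unplanted analytes: K ~ N(4.0, 0.4) mmol/L clipped inside the
alerting thresholds, INR lognormal around 1.1, creatinine lognormal around
0.9 mg/dL, QTc ~ N(420, 25) ms clipped below 450. Ward mix, ICU fraction
(5%) and day-care fraction (10%) are configurable weights.

Two guards keep planted conditions independent: a rule is skipped for a
patient-day when its analytes were already scripted by another rule that
day, or when its drug sets overlap drugs already planted (otherwise one
rule's drugs could repair another rule's deliberately broken conjunct, and
near-misses would no longer be guaranteed negative).

Determinism: each patient draws from a substream spawned from
(seed, patient index), so enlarging the census never reshuffles existing
patients; identical seed and configuration give byte-identical files.

The action-log generator emulates the downstream acceptance study:
channel-stratified actions with configured acceptance, duplicate and
unverifiable probabilities (defaults 0.56/0.14/0.10 for notes,
0.83/0.013/0.25 for phone calls, 0.52 accepted for sequential advice —
the magnitudes of the original service's observed rates, stated once here
as the generator's conditions).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: the overwhelming base rate of benign
patient-days (real action rates are ~7%, synthetic ones are high by
construction), correlated comorbidity (a renally impaired patient is also a
hyperkalemia risk), order churn within a day, free-text documentation, delayed
laboratory delivery, and real ward/drug mixes or 18-month volumes.

## Problem sizes and numerical choices

The default test-suite and acceptance-script runs use censuses of 600–2,000
patient-days and action logs of 300–2,000 actions per channel; recovery
checks use a 3-binomial-standard-error band at those sizes. Percentage
arithmetic goes through `decimal` with explicit half-up rounding to avoid
binary-float artifacts at the .5 boundaries. Evidence equality for
suppression is exact; report generation is pure, so re-running any report on
the same run directory is bit-identical.

## Known limitations

- The shipped rule catalogue is exemplar-sized (17 rules), not a full
  production set; the schema, not the catalogue, is the contribution.
- Interaction severity is taken from the override event; there is no DDI
  severity database.
- `gi_absorption_intact` is an explicit input flag; deriving it from feeding
  status or diagnosis codes is left to upstream adapters.
- Flowchart questions are limited to re-evaluation predicates
  (criteria still met, triggering drug active); richer bedside questions
  (symptoms, care goals) are not structurally available to a rule engine.
- No statistical inference on rates (the evaluation is descriptive), and no
  EHR write-back: notes are log entries.
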