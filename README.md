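# cma — clinical-rule medication surveillance

`cma` is a rule engine for back-office medication surveillance in hospitals,
modelled on the "Check of Medication Appropriateness" style of service: a
pharmacist-facing layer on top of computerized order entry that screens every
non-critically-ill inpatient and day-care admission once a day with *advanced*
clinical rules — if-then triggers that combine medication orders with patient
characteristics (renal function, potassium, INR, neutrophil count, QTc,
overridden drug–drug-interaction alerts) rather than looking at the
prescription alone.

It is aimed at clinical-pharmacy informatics teams who want to prototype,
validate and evaluate such rule sets without access to a production EHR: the
package ships a declarative rule schema with exemplar rules, the daily
screening pass, the pharmacist worklist with duplicate suppression and
flowchart-driven triage (electronic note vs. note plus phone call), the
automatic IV-to-oral sequential-therapy detector, the downstream evaluation
statistics, and a seeded synthetic census generator so everything runs on
data that never existed.

## The model

A **rule** is a conjunction of trigger criteria evaluated per patient-day at
the screening instant (noon), using the most recent observation per analyte
within a staleness window. All threshold comparators are strict — a value
exactly at threshold never fires. Examples shipped in the default rule set:

- renal insufficiency: CrCl < 30 mL/min and an active metformin order, where
  CrCl is the Cockcroft–Gault estimate
  `CrCl = (140 − age) · weight / (72 · SCr)` (× 0.85 for women), overridden
  by a newer measured clearance when one exists;
- QTc prolongation: QTc > 450 ms (men) / 470 ms (women) with an active
  QTc-prolonging drug;
- hyperkalemia: K > 5.5 mmol/L under an ACE inhibitor; hypokalemia:
  K < 3.5 mmol/L under flucloxacillin *without* potassium supplementation;
- supratherapeutic INR (> 4) under a vitamin K antagonist; neutropenia
  (ANC < 1.5 × 10⁹/L) under clozapine;
- restricted dosing/indication (e.g. meropenem ≥ 2 g q8h, linezolid without a
  qualifying indication); overridden very-severe drug–drug interactions with
  both drugs still active.

Drug classes are ATC prefix/code sets defined in the same YAML file as the
rules, so rule files stay portable. Alerts land on a worklist; per-rule
decision-tree flowcharts resolve each entry deterministically to *no action*,
an *electronic note*, or a *note plus phone call*. Acceptance of an action is
classified against the patient's subsequent record: a prescription stop or
dose correction, or a follow-up measurement of the monitored parameter,
within 72 h. Interrater reliability of the triage step is measured with
Cohen's kappa, κ = (p₀ − pₑ)/(1 − pₑ).

## Worked example

```
$ cma simulate --seed 7 --out data
wrote census for 600 patients x 1 day(s) to data
$ cma screen --date 2026-03-01 --in data --out run
screened 600 snapshots: 176 new alerts (0 suppressed), 17 sequential auto-notes, 0 rejected rows
$ cma triage --run run --in data --auto
triage: 176 actions, 0 no-action alerts
$ cma evaluate --run run
```

The simulated census of 600 patients plants each rule's full trigger
conjunction at 2% prevalence per patient-day (and near-misses, which must
never alert, at 2%): screening finds 176 worklist alerts plus 17 automatic
sequential-therapy notes, which bypass the worklist by design. Auto-triage
walks every alert through its flowchart; `evaluate` then reports the action
rates (here 128 notes and 48 phone calls, i.e. 73% / 27% of checked alerts —
far above a real service's ~7% / 1.6%, because a synthetic census plants only
genuine triggers while a real one is dominated by benign patient-days).

```python
>>> from cma import cohen_kappa
>>> cohen_kappa(["p"]*25 + ["n"]*25, ["p"]*20 + ["n"]*5 + ["p"]*10 + ["n"]*15)
0.3999999999999999      # p_o = 0.7, p_e = 0.5
```

## Layout

| module | contents |
| --- | --- |
| `cma.model` | domain types (snapshots, orders, labs, overrides), unit normalization, ATC drug sets |
| `cma.rules` | rule schema, criterion evaluation, Cockcroft–Gault, sequential-therapy detector, screening pass |
| `cma.surveillance` | worklist, duplicate suppression, flowcharts, triage |
| `cma.evaluation` | action-rate reports, 72-h acceptance classification, top-k summaries, Cohen's kappa |
| `cma.synth` | seeded census and action-log generator |
| `cma.fixtures` | published count tables and CSV emitter |
| `cma.io` / `cma.cli` | CSV/JSONL/YAML readers and writers, run directory, `cma` command line |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
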