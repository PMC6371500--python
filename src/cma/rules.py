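"""Declarative clinical rules and their trigger evaluation.

A rule is a conjunction of trigger criteria over one patient snapshot:
'if-then' logic of the form *if CrCl < 30 mL/min AND an active metformin
order, then alert*.  Rules fall into five pharmacotherapeutic categories:

1. overridden very-severe drug–drug interactions,
2. drugs with a restricted indication or dosing,
3. medication potentially leading to biochemical changes (six subcategories:
   renal insufficiency, QTc prolongation, hyper-/hypokalemia,
   supratherapeutic INR, bone-marrow suppression),
4. potential sequential (IV-to-oral) therapy, handled by an automatic note
   that bypasses the pharmacist worklist, and
5. others (e.g. non-crushable drugs via an enteral feeding tube).

All threshold comparators are applied strictly as configured: a value exactly
at threshold does not fire.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .model import (
    Analyte,
    DDISeverity,
    DrugSet,
    MedicationOrder,
    PatientSnapshot,
    Route,
    Sex,
    drug_in_set,
)

logger = logging.getLogger("cma")

#: staleness windows (hours) for most-recent-value semantics.  Fast-moving
#: analytes use 72 h; creatinine 7 days.
DEFAULT_STALENESS_HOURS: dict[str, float] = {
    "serum_creatinine": 168.0,
    "potassium": 72.0,
    "inr": 72.0,
    "anc": 72.0,
    "crcl_measured": 168.0,
    "qtc": 72.0,
}


class RuleCategory(str, enum.Enum):
    ddi_override = "ddi_override"
    restricted_indication_dosing = "restricted_indication_dosing"
    biochemical = "biochemical"
    sequential_therapy = "sequential_therapy"
    other = "other"


class BiochemicalSubcategory(str, enum.Enum):
    renal_insufficiency = "renal_insufficiency"
    qtc_prolongation = "qtc_prolongation"
    hyperkalemia = "hyperkalemia"
    hypokalemia = "hypokalemia"
    supratherapeutic_inr = "supratherapeutic_inr"
    bone_marrow_suppression = "bone_marrow_suppression"


class CriterionKind(str, enum.Enum):
    lab_threshold = "lab_threshold"
    clinical_param_threshold = "clinical_param_threshold"
    drug_present = "drug_present"
    drug_absent = "drug_absent"
    dose_threshold = "dose_threshold"
    route_is = "route_is"
    ddi_override_of = "ddi_override_of"
    indication_not_in = "indication_not_in"
    non_crushable_via_tube = "non_crushable_via_tube"


class Comparator(str, enum.Enum):
    lt = "lt"
    le = "le"
    gt = "gt"
    ge = "ge"
    eq = "eq"

    def apply(self, observed: float, threshold: float) -> bool:
        if self is Comparator.lt:
            return observed < threshold
        if self is Comparator.le:
            return observed <= threshold
        if self is Comparator.gt:
            return observed > threshold
        if self is Comparator.ge:
            return observed >= threshold
        return observed == threshold


class TriggerCriterion(BaseModel):
    """One conjunct of a rule.  ``name`` keys the evidence map and binds the
    ``{name}`` placeholder in the rule's advice template."""

    name: str
    kind: CriterionKind
    analyte: Optional[str] = None  # lab_threshold: analyte code or "crcl"
    param: str = "qtc"  # clinical_param_threshold
    comparator: Optional[Comparator] = None
    threshold: Optional[float] = None
    unit: str = ""
    sex_specific_thresholds: Optional[dict[str, float]] = None
    drug_set_ref: Optional[str] = None
    route: Optional[Route] = None  # route_is / drug_present restriction
    pair_sets: Optional[tuple[str, str]] = None  # ddi_override_of
    allowed_indications: Optional[list[str]] = None  # indication_not_in
    max_interval_hours: Optional[float] = None  # dose_threshold
    staleness_hours: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "TriggerCriterion":
        k = self.kind
        if k in (CriterionKind.lab_threshold, CriterionKind.clinical_param_threshold,
                 CriterionKind.dose_threshold):
            if self.comparator is None or (
                self.threshold is None and self.sex_specific_thresholds is None
            ):
                raise ValueError(f"criterion {self.name!r}: {k.value} needs comparator and threshold")
        if self.sex_specific_thresholds is not None and k is not CriterionKind.clinical_param_threshold:
            raise ValueError(
                f"criterion {self.name!r}: sex_specific_thresholds only valid for clinical_param_threshold"
            )
        if k in (CriterionKind.drug_present, CriterionKind.drug_absent,
                 CriterionKind.dose_threshold, CriterionKind.route_is,
                 CriterionKind.indication_not_in) and not self.drug_set_ref:
            raise ValueError(f"criterion {self.name!r}: {k.value} needs drug_set_ref")
        if k is CriterionKind.ddi_override_of and not self.pair_sets:
            raise ValueError(f"criterion {self.name!r}: ddi_override_of needs pair_sets")
        return self


class RuleDefinition(BaseModel):
    rule_id: str
    category: RuleCategory
    subcategory: Optional[BiochemicalSubcategory] = None
    description: str = ""
    criteria: list[TriggerCriterion] = Field(min_length=1)
    advice_template: str = ""
    escalation: str = "note_only"  # note_only | note_plus_phone
    enabled: bool = True

    @model_validator(mode="after")
    def _check(self) -> "RuleDefinition":
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValueError(f"rule {self.rule_id}: duplicate criterion names")
        if self.escalation not in ("note_only", "note_plus_phone"):
            raise ValueError(f"rule {self.rule_id}: unknown escalation {self.escalation!r}")
        import string
        for _, field, _, _ in string.Formatter().parse(self.advice_template):
            if field and field not in names:
                raise ValueError(
                    f"rule {self.rule_id}: advice placeholder {{{field}}} not bound by any criterion"
                )
        return self


class Alert(BaseModel):
    """One firing of one rule for one patient on one date, with the trigger
    evidence (criterion name -> observed value)."""

    alert_id: str
    rule_id: str
    patient_id: str
    snapshot_date: dt.date
    category: RuleCategory
    ward: str = ""
    triggering_orders: list[str] = Field(default_factory=list)
    triggering_drugs: list[str] = Field(default_factory=list)  # ATC codes
    evidence: dict[str, object] = Field(default_factory=dict)
    status: str = "new"  # new | suppressed_duplicate
    duplicate_of: Optional[str] = None


class AutoNote(BaseModel):
    """Automatic sequential-therapy note (IV-to-oral switch suggestion);
    placed directly in the record, never on the pharmacist worklist."""

    patient_id: str
    snapshot_date: dt.date
    switches: list[dict[str, str]]  # order_id, iv_code, oral_code, drug_name
    text: str


class BioequivalenceTable(BaseModel):
    """IV ATC code -> oral ATC code for bio-equivalent formulations."""

    entries: dict[str, str]

    @model_validator(mode="after")
    def _valid(self) -> "BioequivalenceTable":
        from .model import _check_atc
        for iv, oral in self.entries.items():
            _check_atc(iv)
            _check_atc(oral)
        return self


class RuleConfigError(ValueError):
    """A rule references an undefined drug set or is otherwise inconsistent;
    raised at load time, never during evaluation."""


def validate_ruleset(rules: list[RuleDefinition], drug_sets: dict[str, DrugSet]) -> None:
    seen: set[str] = set()
    for rule in rules:
        if rule.rule_id in seen:
            raise RuleConfigError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)
        for crit in rule.criteria:
            refs = []
            if crit.drug_set_ref:
                refs.append(crit.drug_set_ref)
            if crit.pair_sets:
                refs.extend(crit.pair_sets)
            for ref in refs:
                if ref not in drug_sets:
                    raise RuleConfigError(
                        f"rule {rule.rule_id}, criterion {crit.name!r}: "
                        f"undefined drug set {ref!r}"
                    )


def estimate_crcl(age: float, weight_kg: float, serum_creatinine: float, sex: Sex | str) -> float:
    """Cockcroft–Gault creatinine clearance estimate (mL/min) on actual body
    weight: (140 − age) × weight / (72 × SCr), × 0.85 for women.

    Pediatric patients (< 18 y) are refused — the formula does not apply.
    """
    if age < 18:
        raise ValueError("Cockcroft-Gault not applicable below 18 years")
    if weight_kg <= 0 or serum_creatinine <= 0:
        raise ValueError("weight and serum creatinine must be positive")
    crcl = (140.0 - age) * weight_kg / (72.0 * serum_creatinine)
    if Sex(sex) is Sex.female:
        crcl *= 0.85
    return crcl


def renal_function(snapshot: PatientSnapshot) -> Optional[float]:
    """CrCl (mL/min) for screening: a measured/registered CrCl lab value takes
    precedence when present and newer than the creatinine it would replace;
    otherwise Cockcroft–Gault from the latest serum creatinine."""
    measured = snapshot.latest_lab(
        Analyte.crcl_measured, DEFAULT_STALENESS_HOURS["crcl_measured"]
    )
    scr = snapshot.latest_lab(
        Analyte.serum_creatinine, DEFAULT_STALENESS_HOURS["serum_creatinine"]
    )
    if measured is not None and (scr is None or measured.timestamp >= scr.timestamp):
        return measured.value
    if scr is None or snapshot.sex is None or snapshot.weight_kg is None:
        if measured is not None:
            return measured.value
        return None
    if snapshot.age < 18:
        return None
    return estimate_crcl(snapshot.age, snapshot.weight_kg, scr.value, snapshot.sex)


def _active_in_set(
    snapshot: PatientSnapshot, dset: DrugSet, route: Optional[Route] = None
) -> list[MedicationOrder]:
    return [
        o
        for o in snapshot.active_orders()
        if drug_in_set(o.drug_code, dset) and (route is None or o.route is route)
    ]


def _eval_criterion(
    crit: TriggerCriterion,
    snapshot: PatientSnapshot,
    drug_sets: dict[str, DrugSet],
) -> Optional[tuple[object, list[MedicationOrder]]]:
    """Return (observed evidence, implicated orders) when the criterion holds,
    else None."""
    kind = crit.kind

    if kind is CriterionKind.lab_threshold:
        if crit.analyte in ("crcl", "crcl_measured"):
            observed = renal_function(snapshot)
        else:
            analyte = Analyte(crit.analyte)
            stale = crit.staleness_hours or DEFAULT_STALENESS_HOURS.get(analyte.value)
            lab = snapshot.latest_lab(analyte, stale)
            observed = lab.value if lab else None
        if observed is None:
            return None
        return (observed, []) if crit.comparator.apply(observed, crit.threshold) else None

    if kind is CriterionKind.clinical_param_threshold:
        stale = crit.staleness_hours or DEFAULT_STALENESS_HOURS.get(crit.param)
        param = snapshot.latest_param(crit.param, stale)
        if param is None:
            return None
        threshold = crit.threshold
        if crit.sex_specific_thresholds is not None:
            if snapshot.sex is None:
                threshold = min(crit.sex_specific_thresholds.values())
                logger.warning(
                    "patient %s: sex unknown, using stricter threshold %s for %s",
                    snapshot.patient_id, threshold, crit.param,
                )
            else:
                threshold = crit.sex_specific_thresholds[snapshot.sex.value]
        return (param.value, []) if crit.comparator.apply(param.value, threshold) else None

    if kind in (CriterionKind.drug_present, CriterionKind.route_is):
        matches = _active_in_set(snapshot, drug_sets[crit.drug_set_ref], crit.route)
        if not matches:
            return None
        return (sorted({o.drug_name or o.drug_code for o in matches}), matches)

    if kind is CriterionKind.drug_absent:
        matches = _active_in_set(snapshot, drug_sets[crit.drug_set_ref], crit.route)
        return ("absent", []) if not matches else None

    if kind is CriterionKind.dose_threshold:
        hits = [
            o
            for o in _active_in_set(snapshot, drug_sets[crit.drug_set_ref], crit.route)
            if crit.comparator.apply(o.dose_mg, crit.threshold)
            and (crit.max_interval_hours is None or o.frequency_hours <= crit.max_interval_hours)
        ]
        if not hits:
            return None
        return (max(o.dose_mg for o in hits), hits)

    if kind is CriterionKind.indication_not_in:
        allowed = set(crit.allowed_indications or [])
        hits, undocumented = [], False
        for o in _active_in_set(snapshot, drug_sets[crit.drug_set_ref], crit.route):
            if o.indication_code is None:
                # conservative: an unverified indication is flagged for review
                hits.append(o)
                undocumented = True
            elif o.indication_code not in allowed:
                hits.append(o)
        if not hits:
            return None
        if undocumented:
            logger.info(
                "patient %s: indication undocumented for %s",
                snapshot.patient_id, [o.order_id for o in hits],
            )
        observed = sorted({o.indication_code or "indication undocumented" for o in hits})
        return (observed, hits)

    if kind is CriterionKind.non_crushable_via_tube:
        hits = [
            o
            for o in snapshot.active_orders()
            if o.route is Route.enteral_tube and not o.crushable
        ]
        if not hits:
            return None
        return (sorted({o.drug_name or o.drug_code for o in hits}), hits)

    if kind is CriterionKind.ddi_override_of:
        set_a, set_b = (drug_sets[s] for s in crit.pair_sets)
        active = snapshot.active_orders()
        for ev in snapshot.overrides:
            if ev.severity is not DDISeverity.very_severe:
                continue
            pairs = [(ev.drug_a, ev.drug_b), (ev.drug_b, ev.drug_a)]
            if not any(drug_in_set(a, set_a) and drug_in_set(b, set_b) for a, b in pairs):
                continue
            hits_a = [o for o in active if o.drug_code == ev.drug_a]
            hits_b = [o for o in active if o.drug_code == ev.drug_b]
            if hits_a and hits_b:  # both drugs still active at screening
                return (f"{ev.drug_a}+{ev.drug_b}", hits_a + hits_b)
        return None

    raise AssertionError(f"unhandled criterion kind {kind}")


def evaluate_rule(
    rule: RuleDefinition,
    snapshot: PatientSnapshot,
    drug_sets: dict[str, DrugSet],
) -> Optional[Alert]:
    """Evaluate one rule against one snapshot.

    Returns an :class:`Alert` iff ALL criteria hold at the screening instant
    (conjunctive semantics, most-recent-value lookups); otherwise None.  Pure:
    no side effects on the snapshot.
    """
    if not rule.enabled or not snapshot.eligible:
        return None
    evidence: dict[str, object] = {}
    implicated: list[MedicationOrder] = []
    for crit in rule.criteria:
        result = _eval_criterion(crit, snapshot, drug_sets)
        if result is None:
            return None
        observed, orders = result
        evidence[crit.name] = observed
        implicated.extend(orders)
    order_ids = sorted({o.order_id for o in implicated})
    drugs = sorted({o.drug_code for o in implicated})
    return Alert(
        alert_id=f"{snapshot.snapshot_date.isoformat()}:{snapshot.patient_id}:{rule.rule_id}",
        rule_id=rule.rule_id,
        patient_id=snapshot.patient_id,
        snapshot_date=snapshot.snapshot_date,
        category=rule.category,
        ward=snapshot.ward,
        triggering_orders=order_ids,
        triggering_drugs=drugs,
        evidence=evidence,
    )


def detect_sequential_therapy(
    snapshot: PatientSnapshot, table: BioequivalenceTable
) -> Optional[AutoNote]:
    """Automatic IV-to-oral switch detector.

    Fires iff gastrointestinal absorption is presumed intact AND at least one
    active IV order has a bio-equivalent oral form in the table.  The note
    lists each switchable order with its oral equivalent and bypasses the
    pharmacist worklist entirely.
    """
    if not snapshot.eligible or not snapshot.gi_absorption_intact:
        return None
    switches = [
        {
            "order_id": o.order_id,
            "iv_code": o.drug_code,
            "oral_code": table.entries[o.drug_code],
            "drug_name": o.drug_name or o.drug_code,
        }
        for o in snapshot.active_orders()
        if o.route is Route.iv and o.drug_code in table.entries
    ]
    if not switches:
        return None
    switches.sort(key=lambda s: s["order_id"])
    lines = [
        f"Consider IV-to-oral switch: {s['drug_name']} ({s['iv_code']}) -> oral ({s['oral_code']})"
        for s in switches
    ]
    return AutoNote(
        patient_id=snapshot.patient_id,
        snapshot_date=snapshot.snapshot_date,
        switches=switches,
        text="; ".join(lines),
    )


def screen_population(
    snapshots: list[PatientSnapshot],
    rules: list[RuleDefinition],
    drug_sets: dict[str, DrugSet],
    bioequivalence: BioequivalenceTable,
    date: dt.date,
) -> tuple[list[Alert], list[AutoNote]]:
    """Daily screening pass over a census.

    All snapshots must share ``date``.  Ineligible snapshots (ICU, discharged)
    are skipped with a logged message.  Output order is deterministic:
    (patient_id, rule_id).
    """
    bad = [s.patient_id for s in snapshots if s.snapshot_date != date]
    if bad:
        raise ValueError(f"snapshots not on screening date {date}: {bad[:5]}")
    alerts: list[Alert] = []
    auto_notes: list[AutoNote] = []
    active_rules = [
        r for r in rules if r.enabled and r.category is not RuleCategory.sequential_therapy
    ]
    for snapshot in sorted(snapshots, key=lambda s: s.patient_id):
        if not snapshot.eligible:
            logger.info(
                "skipping patient %s (%s): not screened",
                snapshot.patient_id, snapshot.admission_class.value,
            )
            continue
        for rule in sorted(active_rules, key=lambda r: r.rule_id):
            alert = evaluate_rule(rule, snapshot, drug_sets)
            if alert is not None:
                alerts.append(alert)
        note = detect_sequential_therapy(snapshot, bioequivalence)
        if note is not None:
            auto_notes.append(note)
    return alerts, auto_notes
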