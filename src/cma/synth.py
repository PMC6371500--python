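"""Seeded synthetic hospital census and action-log generator.

Emulates the inputs of a daily medication-appropriateness screening run: a
census of non-critically-ill inpatients and day-care admissions with
medication orders, laboratory results, QTc measurements and CDSS
drug–drug-interaction override events.  For each enabled rule, a patient-day
contains that rule's *full* trigger conjunction with the configured
prevalence, and a *near-miss* (all conjuncts but one, the broken one chosen
uniformly) with the configured near-miss fraction — near-misses must never
alert, which is the generator's built-in specificity probe.

Determinism: a single integer seed drives the run; each patient draws from a
substream spawned from (seed, patient_index), so enlarging the census never
reshuffles existing patients.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .model import CANONICAL_UNITS, Analyte, DrugSet, Route, Sex, drug_in_set
from .rules import (
    BioequivalenceTable,
    Comparator,
    CriterionKind,
    RuleCategory,
    RuleDefinition,
    TriggerCriterion,
    validate_ruleset,
)

_DRUG_NAMES = {
    "A10BA02": "metformin", "C09AA02": "enalapril", "C09AA03": "lisinopril",
    "J01CF05": "flucloxacillin", "B01AA03": "warfarin", "B01AA07": "acenocoumarol",
    "N05AH02": "clozapine", "N05AD01": "haloperidol", "J01MA12": "levofloxacin",
    "J01MA14": "moxifloxacin", "A04AA01": "ondansetron", "J02AC01": "fluconazole",
    "C07AA07": "sotalol", "J01DH02": "meropenem", "J01XB01": "colistin",
    "J01XX08": "linezolid", "J01CA17": "temocillin", "J04AB02": "rifampicin",
    "N03AG01": "valproic acid", "B01AF01": "rivaroxaban", "B01AF02": "apixaban",
    "B01AB05": "enoxaparin", "B01AB10": "tinzaparin", "C01BD01": "amiodarone",
    "J01MA02": "ciprofloxacin", "J01FF01": "clindamycin", "J01XD01": "metronidazole",
    "J01AA02": "doxycycline", "N02BE01": "paracetamol", "A02BC01": "omeprazole",
    "A12BA01": "potassium chloride", "A03FA03": "domperidone", "N05BB01": "hydroxyzine",
}

_WARDS_DEFAULT = {
    "ED": 0.18, "Cardiac sg": 0.10, "Vascular sg": 0.10, "Nephrology": 0.08,
    "Pneumology": 0.09, "Internal medicine": 0.15, "Trauma sg": 0.10,
    "Urology": 0.10, "Thoracic sg": 0.10,
}

_LAB_BASELINES_DEFAULT = {
    "potassium": {"dist": "normal", "mean": 4.0, "sd": 0.4},
    "inr": {"dist": "lognormal", "mean": 1.1, "sd": 0.15},
    "serum_creatinine": {"dist": "lognormal", "mean": 0.9, "sd": 0.2},
    "qtc": {"dist": "normal", "mean": 420.0, "sd": 25.0},
}


class GenerationError(ValueError):
    """The configuration cannot be realised (e.g. a trigger is requested for
    a rule whose drugs cannot be instantiated)."""


class ChannelBehavior(BaseModel):
    """Post-action behaviour of one action channel: probability the action is
    followed by a qualifying event within 72 h, plus exclusion rates."""

    p_accept: float = Field(ge=0, le=1)
    p_duplicate: float = Field(default=0.0, ge=0, le=1)
    p_unverifiable: float = Field(default=0.0, ge=0, le=1)
    n_actions: int = Field(default=300, ge=0)


class GeneratorConfig(BaseModel):
    n_patients: int = 600
    n_days: int = 1
    start_date: dt.date = dt.date(2026, 3, 1)
    seed: int = 0
    ward_distribution: dict[str, float] = Field(default_factory=lambda: dict(_WARDS_DEFAULT))
    icu_fraction: float = Field(default=0.05, ge=0, le=1)
    day_care_fraction: float = Field(default=0.10, ge=0, le=1)
    #: per-rule probability that a patient-day carries the full trigger
    #: conjunction; rules absent from the map use ``default_prevalence``.
    rule_prevalence: dict[str, float] = Field(default_factory=dict)
    default_prevalence: float = Field(default=0.02, ge=0, le=1)
    sequential_prevalence: float = Field(default=0.05, ge=0, le=1)
    near_miss_fraction: float = Field(default=0.02, ge=0, le=1)
    lab_baselines: dict[str, dict] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _LAB_BASELINES_DEFAULT.items()}
    )
    #: acceptance behaviour per channel; the defaults state the conditions the
    #: generator emulates (note 0.56, phone 0.83, sequential 0.52 accepted).
    acceptance: dict[str, ChannelBehavior] = Field(
        default_factory=lambda: {
            "note": ChannelBehavior(p_accept=0.56, p_duplicate=0.14, p_unverifiable=0.10),
            "note_plus_phone": ChannelBehavior(p_accept=0.83, p_duplicate=0.013, p_unverifiable=0.25),
            "sequential": ChannelBehavior(p_accept=0.52, n_actions=341),
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for rid, p in self.rule_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {rid!r} outside [0, 1]")
        if not self.ward_distribution:
            raise ValueError("ward_distribution must be non-empty")
        return self

    def prevalence(self, rule_id: str) -> float:
        return self.rule_prevalence.get(rule_id, self.default_prevalence)


@dataclasses.dataclass
class CensusFrames:
    """The five census tables, one row per record, CSV-ready."""

    patients: pd.DataFrame
    orders: pd.DataFrame
    labs: pd.DataFrame
    params: pd.DataFrame
    overrides: pd.DataFrame

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients, "orders": self.orders, "labs": self.labs,
            "params": self.params, "overrides": self.overrides,
        }


def _pad_atc(prefix: str) -> str:
    return prefix + {1: "01AA01", 3: "AA01", 4: "A01", 5: "01", 7: ""}[len(prefix)]


def _pick_code(rng: np.random.Generator, dset: DrugSet) -> str:
    if dset.explicit_codes:
        return dset.explicit_codes[int(rng.integers(len(dset.explicit_codes)))]
    return _pad_atc(dset.atc_prefixes[int(rng.integers(len(dset.atc_prefixes)))])


class _PatientDay:
    """Mutable accumulator for one patient-day's planted records."""

    def __init__(self, pid: str, date: dt.date, rng: np.random.Generator):
        self.pid = pid
        self.date = date
        self.rng = rng
        self.noon = dt.datetime.combine(date, dt.time(12, 0))
        self.orders: list[dict] = []
        self.labs: list[dict] = []
        self.params: list[dict] = []
        self.overrides: list[dict] = []
        self._order_seq = 0
        self.planted_analytes: set[str] = set()
        self.planted_codes: set[str] = set()  # codes added by rule planting
        self.gi_absorption_intact = False

    def add_order(
        self,
        code: str,
        route: Route = Route.oral,
        dose_mg: float = 500.0,
        frequency_hours: float = 24.0,
        crushable: bool = True,
        indication: Optional[str] = None,
        stopped_before_noon: bool = False,
    ) -> str:
        self._order_seq += 1
        oid = f"{self.pid}-{self.date.isoformat()}-o{self._order_seq}"
        start = dt.datetime.combine(self.date, dt.time(0, 0)) - dt.timedelta(
            days=int(self.rng.integers(0, 3))
        )
        stop = self.noon - dt.timedelta(hours=2) if stopped_before_noon else None
        self.orders.append(
            {
                "patient_id": self.pid, "order_id": oid, "drug_code": code,
                "drug_name": _DRUG_NAMES.get(code, code), "dose_mg": dose_mg,
                "frequency_hours": frequency_hours, "route": route.value,
                "start": start.isoformat(), "stop": stop.isoformat() if stop else "",
                "crushable": crushable,
                "indication_code": indication or "",
            }
        )
        self.planted_codes.add(code)
        return oid

    def add_lab(self, analyte: str, value: float, hour: int = 10) -> None:
        self.labs.append(
            {
                "patient_id": self.pid, "analyte": analyte, "value": round(value, 4),
                "unit": CANONICAL_UNITS[Analyte(analyte)],
                "timestamp": dt.datetime.combine(self.date, dt.time(hour, 0)).isoformat(),
            }
        )
        self.planted_analytes.add(analyte)

    def add_param(self, kind: str, value: float, hour: int = 10) -> None:
        self.params.append(
            {
                "patient_id": self.pid, "kind": kind, "value": round(value, 1),
                "timestamp": dt.datetime.combine(self.date, dt.time(hour, 0)).isoformat(),
            }
        )
        self.planted_analytes.add(kind)

    def add_override(self, a: str, b: str, severity: str = "very_severe") -> None:
        self.overrides.append(
            {
                "patient_id": self.pid, "drug_a": a, "drug_b": b, "severity": severity,
                "motivation": "benefit outweighs risk" if severity == "very_severe" else "",
                "physician_id": f"md{int(self.rng.integers(100)):03d}",
                "timestamp": dt.datetime.combine(self.date, dt.time(9, 0)).isoformat(),
            }
        )


def _violating_value(rng: np.random.Generator, comparator: Comparator, threshold: float) -> float:
    margin = float(rng.uniform(0.05, 0.35)) * abs(threshold)
    if comparator in (Comparator.lt, Comparator.le):
        return max(threshold - margin, threshold * 0.1)
    return threshold + margin


def _plant_criterion(
    day: _PatientDay,
    crit: TriggerCriterion,
    drug_sets: dict[str, DrugSet],
    sex: Sex,
    *,
    broken: bool,
) -> None:
    """Materialise one criterion in the patient-day's records; when ``broken``
    the records are placed exactly at / on the safe side of the trigger."""
    rng = day.rng
    kind = crit.kind

    if kind is CriterionKind.lab_threshold:
        analyte = "crcl_measured" if crit.analyte in ("crcl", "crcl_measured") else crit.analyte
        value = (
            float(crit.threshold)  # strict comparators: at-threshold never fires
            if broken
            else _violating_value(rng, crit.comparator, crit.threshold)
        )
        day.add_lab(analyte, value)
        return

    if kind is CriterionKind.clinical_param_threshold:
        threshold = crit.threshold
        if crit.sex_specific_thresholds is not None:
            threshold = crit.sex_specific_thresholds[sex.value]
        value = float(threshold) if broken else _violating_value(rng, crit.comparator, threshold)
        day.add_param(crit.param, value)
        return

    if kind in (CriterionKind.drug_present, CriterionKind.route_is):
        if broken:
            return  # drug simply absent
        route = crit.route or Route.oral
        day.add_order(_pick_code(rng, drug_sets[crit.drug_set_ref]), route=route)
        return

    if kind is CriterionKind.drug_absent:
        if broken:  # defeater present
            day.add_order(_pick_code(rng, drug_sets[crit.drug_set_ref]))
        return

    if kind is CriterionKind.dose_threshold:
        dose = crit.threshold if not broken else crit.threshold * 0.5
        day.add_order(
            _pick_code(rng, drug_sets[crit.drug_set_ref]),
            route=Route.iv,
            dose_mg=float(dose),
            frequency_hours=float(crit.max_interval_hours or 8.0),
        )
        return

    if kind is CriterionKind.indication_not_in:
        indication = (
            (crit.allowed_indications or ["ANY"])[0]
            if broken
            else ("" if rng.random() < 0.5 else "UNRESTRICTED_USE")
        )
        day.add_order(
            _pick_code(rng, drug_sets[crit.drug_set_ref]),
            route=Route.iv,
            indication=indication or None,
        )
        return

    if kind is CriterionKind.non_crushable_via_tube:
        day.add_order(
            "A02BC01", route=Route.enteral_tube, crushable=bool(broken)
        )
        return

    if kind is CriterionKind.ddi_override_of:
        set_a, set_b = (drug_sets[s] for s in crit.pair_sets)
        code_a, code_b = _pick_code(rng, set_a), _pick_code(rng, set_b)
        if code_a == code_b:  # overlapping sets: force distinct drugs
            codes = set_a.explicit_codes + set_b.explicit_codes
            code_b = next((c for c in codes if c != code_a), code_b)
        if broken and rng.random() < 0.5:
            # broken variant 1: interaction overridden but not very severe
            day.add_order(code_a)
            day.add_order(code_b)
            day.add_override(code_a, code_b, severity="severe")
        else:
            day.add_order(code_a)
            day.add_order(code_b, stopped_before_noon=broken)
            day.add_override(code_a, code_b, severity="very_severe")
        return

    raise GenerationError(f"cannot plant criterion kind {kind}")


def _rule_sets(rule: RuleDefinition, drug_sets: dict[str, DrugSet]) -> list[DrugSet]:
    refs: list[DrugSet] = []
    for c in rule.criteria:
        if c.drug_set_ref:
            refs.append(drug_sets[c.drug_set_ref])
        if c.pair_sets:
            refs.extend(drug_sets[s] for s in c.pair_sets)
    return refs


def _candidate_codes(sets: list[DrugSet]) -> set[str]:
    codes: set[str] = set()
    for s in sets:
        codes.update(s.explicit_codes)
        codes.update(_pad_atc(p) for p in s.atc_prefixes)
    return codes


def _baseline(rng: np.random.Generator, spec: dict) -> float:
    if spec["dist"] == "normal":
        return float(rng.normal(spec["mean"], spec["sd"]))
    if spec["dist"] == "lognormal":
        sigma = spec["sd"] / spec["mean"]
        return float(rng.lognormal(np.log(spec["mean"]) - sigma**2 / 2, sigma))
    raise GenerationError(f"unknown baseline distribution {spec['dist']!r}")


def generate_census(
    config: GeneratorConfig,
    rules: list[RuleDefinition],
    drug_sets: dict[str, DrugSet],
    bioequivalence: BioequivalenceTable,
) -> CensusFrames:
    """Generate the five census tables for ``config.n_days`` consecutive days.

    Raises :class:`GenerationError` when a requested trigger cannot be
    realised (unknown rule id, empty drug set, unplantable criterion).
    """
    validate_ruleset(rules, drug_sets)
    by_id = {r.rule_id: r for r in rules}
    for rid in config.rule_prevalence:
        if rid not in by_id:
            raise GenerationError(f"prevalence configured for unknown rule {rid!r}")
    plantable = [
        r for r in rules
        if r.enabled and r.category is not RuleCategory.sequential_therapy
    ]
    if config.sequential_prevalence > 0 and not bioequivalence.entries:
        raise GenerationError("sequential prevalence > 0 but bioequivalence table is empty")

    wards = list(config.ward_distribution)
    ward_p = np.array([config.ward_distribution[w] for w in wards], dtype=float)
    ward_p = ward_p / ward_p.sum()

    patients, orders, labs, params, overrides = [], [], [], [], []
    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        pid = f"p{i:05d}"
        age = int(rng.integers(18, 91))
        sex = Sex.male if rng.random() < 0.5 else Sex.female
        weight = float(np.clip(rng.normal(75, 15), 42, 140))
        ward = wards[int(rng.choice(len(wards), p=ward_p))]
        u = rng.random()
        if u < config.icu_fraction:
            adm = "icu"
        elif u < config.icu_fraction + config.day_care_fraction:
            adm = "day_care"
        else:
            adm = "inpatient_non_icu"

        for d in range(config.n_days):
            date = config.start_date + dt.timedelta(days=d)
            day = _PatientDay(pid, date, rng)
            # background therapy (non-triggering; not counted as planted)
            day.add_order("N02BE01", route=Route.oral, dose_mg=1000, frequency_hours=8)
            day.planted_codes.clear()
            day_sets: list[DrugSet] = []
            planted_rules: list[tuple[RuleDefinition, bool]] = []
            for rule in plantable:
                roll = rng.random()
                p = config.prevalence(rule.rule_id)
                if roll < p:
                    planted_rules.append((rule, False))
                elif roll < p + config.near_miss_fraction:
                    planted_rules.append((rule, True))
            for rule, near_miss in planted_rules:
                analytes_needed = {
                    ("crcl_measured" if c.analyte in ("crcl", "crcl_measured") else (c.analyte or c.param))
                    for c in rule.criteria
                    if c.kind in (CriterionKind.lab_threshold, CriterionKind.clinical_param_threshold)
                }
                if analytes_needed & day.planted_analytes:
                    continue  # analyte already scripted by another rule today
                refs = _rule_sets(rule, drug_sets)
                # drug-level interference guard: never let one rule's drugs
                # repair (or defeat) another rule's planted conjunction
                if any(drug_in_set(code, s) for code in day.planted_codes for s in refs):
                    continue
                if any(drug_in_set(code, s) for code in _candidate_codes(refs) for s in day_sets):
                    continue
                broken_idx = int(rng.integers(len(rule.criteria))) if near_miss else -1
                for j, crit in enumerate(rule.criteria):
                    _plant_criterion(day, crit, drug_sets, sex, broken=(j == broken_idx))
                day_sets.extend(refs)
            # sequential-therapy state (skipped when its drugs would collide
            # with a rule planted today, or vice versa)
            seq_codes = set(bioequivalence.entries)
            seq_conflict = bool(day.planted_codes & seq_codes) or any(
                drug_in_set(c, s) for c in seq_codes for s in day_sets
            )
            seq_roll = rng.random() if not seq_conflict else 1.0
            if seq_roll < config.sequential_prevalence:
                day.gi_absorption_intact = True
                iv_codes = sorted(bioequivalence.entries)
                day.add_order(
                    iv_codes[int(rng.integers(len(iv_codes)))], route=Route.iv,
                    dose_mg=500, frequency_hours=12,
                )
            elif seq_roll < config.sequential_prevalence + config.near_miss_fraction:
                # near-miss: IV bio-equivalent drug but absorption not intact
                iv_codes = sorted(bioequivalence.entries)
                day.add_order(
                    iv_codes[int(rng.integers(len(iv_codes)))], route=Route.iv,
                    dose_mg=500, frequency_hours=12,
                )
            # baseline labs for analytes not scripted by a rule today
            for analyte, spec in config.lab_baselines.items():
                if analyte in day.planted_analytes:
                    continue
                value = _baseline(rng, spec)
                if analyte == "qtc":
                    day.add_param("qtc", float(np.clip(value, 350, 449)), hour=8)
                elif analyte == "potassium":
                    day.add_lab(analyte, float(np.clip(value, 3.55, 5.45)), hour=8)
                elif analyte == "inr":
                    day.add_lab(analyte, float(np.clip(value, 0.8, 3.9)), hour=8)
                else:
                    day.add_lab(analyte, max(value, 0.3), hour=8)

            patients.append(
                {
                    "patient_id": pid, "snapshot_date": date.isoformat(), "age": age,
                    "sex": sex.value, "weight_kg": round(weight, 1), "ward": ward,
                    "admission_class": adm,
                    "gi_absorption_intact": day.gi_absorption_intact,
                }
            )
            orders.extend(day.orders)
            labs.extend(day.labs)
            params.extend(day.params)
            overrides.extend(day.overrides)

    return CensusFrames(
        patients=pd.DataFrame(patients),
        orders=pd.DataFrame(orders, columns=[
            "patient_id", "order_id", "drug_code", "drug_name", "dose_mg",
            "frequency_hours", "route", "start", "stop", "crushable", "indication_code",
        ]),
        labs=pd.DataFrame(labs, columns=["patient_id", "analyte", "value", "unit", "timestamp"]),
        params=pd.DataFrame(params, columns=["patient_id", "kind", "value", "timestamp"]),
        overrides=pd.DataFrame(overrides, columns=[
            "patient_id", "drug_a", "drug_b", "severity", "motivation",
            "physician_id", "timestamp",
        ]),
    )


def generate_action_log(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Channel-stratified pharmacist actions plus each patient's subsequent
    events, for exercising the 72-hour acceptance classification.

    Returns (actions, events).  Actions carry channel, duplicate flag and
    timestamps; events carry (action_id, kind, timestamp).  Classifying the
    output recovers the configured per-channel acceptance and exclusion
    probabilities within binomial sampling error.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1_000_003,)))
    base = dt.datetime.combine(config.start_date, dt.time(12, 0))
    actions, events = [], []
    qualifying = ["stop", "dose_correction", "followup_measurement", "modification"]
    for channel, behavior in sorted(config.acceptance.items()):
        for i in range(behavior.n_actions):
            aid = f"{channel}-{i:04d}"
            t0 = base + dt.timedelta(hours=float(rng.uniform(0, 24 * 30)))
            is_dup = bool(rng.random() < behavior.p_duplicate)
            actions.append(
                {
                    "action_id": aid, "channel": channel,
                    "disposition": "note_plus_phone" if channel == "note_plus_phone" else "note",
                    "timestamp": t0.isoformat(), "is_duplicate": is_dup,
                }
            )
            if is_dup:
                continue
            if rng.random() < behavior.p_unverifiable:
                events.append(
                    {
                        "action_id": aid, "kind": "discharge",
                        "timestamp": (t0 + dt.timedelta(hours=float(rng.uniform(1, 24)))).isoformat(),
                    }
                )
                continue
            if rng.random() < behavior.p_accept:
                kind = qualifying[int(rng.integers(len(qualifying)))]
                events.append(
                    {
                        "action_id": aid, "kind": kind,
                        "timestamp": (t0 + dt.timedelta(hours=float(rng.uniform(1, 71)))).isoformat(),
                    }
                )
            elif rng.random() < 0.3:
                # late modification: outside the window, hence not accepted
                events.append(
                    {
                        "action_id": aid, "kind": "modification",
                        "timestamp": (t0 + dt.timedelta(hours=float(rng.uniform(73, 240)))).isoformat(),
                    }
                )
    return (
        pd.DataFrame(actions, columns=["action_id", "channel", "disposition", "timestamp", "is_duplicate"]),
        pd.DataFrame(events, columns=["action_id", "kind", "timestamp"]),
    )
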