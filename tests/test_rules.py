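import datetime as dt

import pytest

from cma.rules import (
    RuleCategory,
    detect_sequential_therapy,
    estimate_crcl,
    evaluate_rule,
    screen_population,
)
from conftest import DATE, NOON, lab, make_order, make_snapshot, override, qtc


def rule(ruleset, rid):
    return ruleset.rules_by_id[rid]


# --------------------------------------------------------------------------
# creatinine clearance


def test_cockcroft_gault_worked_examples():
    assert estimate_crcl(60, 72.0, 1.0, "male") == pytest.approx(80.0)
    assert estimate_crcl(60, 72.0, 1.0, "female") == pytest.approx(68.0)


@pytest.mark.parametrize("age,weight,scr,sex", [(60, 72, 1.0, "male"), (45, 90, 0.7, "female")])
def test_doubling_creatinine_halves_clearance(age, weight, scr, sex):
    assert estimate_crcl(age, weight, 2 * scr, sex) == pytest.approx(
        estimate_crcl(age, weight, scr, sex) / 2
    )


def test_crcl_refuses_pediatric_and_nonpositive():
    with pytest.raises(ValueError):
        estimate_crcl(17, 60, 1.0, "male")
    with pytest.raises(ValueError):
        estimate_crcl(40, -1, 1.0, "male")
    with pytest.raises(ValueError):
        estimate_crcl(40, 70, 0.0, "male")


def test_measured_crcl_overrides_estimate(ruleset):
    # Cockcroft-Gault would give 80 mL/min; a newer measured CrCl of 25 wins
    snap = make_snapshot(
        labs=[lab("serum_creatinine", 1.0, 5), lab("crcl_measured", 25.0, 2)],
        orders=[make_order("A10BA02")],
    )
    assert evaluate_rule(rule(ruleset, "renal_metformin"), snap, ruleset.drug_sets)
    # older measured value loses to the newer creatinine-based estimate
    snap2 = make_snapshot(
        labs=[lab("serum_creatinine", 1.0, 2), lab("crcl_measured", 25.0, 5)],
        orders=[make_order("A10BA02")],
    )
    assert evaluate_rule(rule(ruleset, "renal_metformin"), snap2, ruleset.drug_sets) is None


# --------------------------------------------------------------------------
# biochemical trigger examples


def test_renal_metformin_triggers_below_30(ruleset):
    snap = make_snapshot(
        labs=[lab("crcl_measured", 25.0)], orders=[make_order("A10BA02")]
    )
    alert = evaluate_rule(rule(ruleset, "renal_metformin"), snap, ruleset.drug_sets)
    assert alert is not None
    assert alert.evidence["crcl"] == 25.0
    assert "o-A10BA02-oral" in alert.triggering_orders


def test_hyperkalemia_with_ace_inhibitor(ruleset):
    snap = make_snapshot(labs=[lab("potassium", 5.8)], orders=[make_order("C09AA02")])
    alert = evaluate_rule(rule(ruleset, "hyperkalemia_ace"), snap, ruleset.drug_sets)
    assert alert is not None and alert.evidence["k"] == 5.8


def test_hypokalemia_defeated_by_potassium_supplementation(ruleset):
    r = rule(ruleset, "hypokalemia_flucloxacillin")
    base = dict(labs=[lab("potassium", 3.2)])
    with_supplement = make_snapshot(
        orders=[make_order("J01CF05"), make_order("A12BA01")], **base
    )
    assert evaluate_rule(r, with_supplement, ruleset.drug_sets) is None
    without = make_snapshot(orders=[make_order("J01CF05")], **base)
    assert evaluate_rule(r, without, ruleset.drug_sets) is not None


def test_supratherapeutic_inr_with_vka(ruleset):
    r = rule(ruleset, "supratherapeutic_inr_vka")
    fires = make_snapshot(labs=[lab("inr", 4.5)], orders=[make_order("B01AA04")])
    assert evaluate_rule(r, fires, ruleset.drug_sets) is not None
    no_fire = make_snapshot(labs=[lab("inr", 4.0)], orders=[make_order("B01AA04")])
    assert evaluate_rule(r, no_fire, ruleset.drug_sets) is None


def test_neutropenia_with_clozapine(ruleset):
    snap = make_snapshot(labs=[lab("anc", 1.2)], orders=[make_order("N05AH02")])
    assert evaluate_rule(rule(ruleset, "neutropenia_clozapine"), snap, ruleset.drug_sets)


def test_ineligible_snapshot_never_alerts(ruleset):
    snap = make_snapshot(
        admission="icu", labs=[lab("inr", 9.0)], orders=[make_order("B01AA03")]
    )
    assert evaluate_rule(rule(ruleset, "supratherapeutic_inr_vka"), snap, ruleset.drug_sets) is None


# --------------------------------------------------------------------------
# QTc rule (sex-specific thresholds)


@pytest.mark.parametrize(
    "qtc_ms, sex, drug, fires",
    [
        (480, "male", "N05AD01", True),    # haloperidol above male threshold
        (460, "female", "N05AD01", False),  # below the female 470 ms threshold
        (460, "male", "N05AD01", True),
        (480, "male", None, False),         # no QTc-prolonging drug active
        (480, "female", "N05AD01", True),
    ],
)
def test_qtc_rule_sex_thresholds(ruleset, qtc_ms, sex, drug, fires):
    orders = [make_order(drug)] if drug else []
    snap = make_snapshot(sex=sex, params=[qtc(qtc_ms)], orders=orders)
    alert = evaluate_rule(rule(ruleset, "qtc_prolonging_drug"), snap, ruleset.drug_sets)
    assert (alert is not None) is fires


def test_qtc_missing_sex_uses_stricter_threshold(ruleset):
    snap = make_snapshot(sex=None, params=[qtc(460)], orders=[make_order("N05AD01")])
    assert evaluate_rule(rule(ruleset, "qtc_prolonging_drug"), snap, ruleset.drug_sets)


# --------------------------------------------------------------------------
# restricted indication / dosing


@pytest.mark.parametrize(
    "dose, freq, fires",
    [(2000, 8, True), (2000, 6, True), (1000, 8, False), (2000, 12, False)],
)
def test_meropenem_high_dose(ruleset, dose, freq, fires):
    snap = make_snapshot(orders=[make_order("J01DH02", route="iv", dose=dose, freq=freq)])
    alert = evaluate_rule(rule(ruleset, "meropenem_high_dose"), snap, ruleset.drug_sets)
    assert (alert is not None) is fires


@pytest.mark.parametrize(
    "indication, fires",
    [("OTHER_INFECTION", True), (None, True), ("MRSA_INFECTION", False)],
)
def test_linezolid_restricted_indication(ruleset, indication, fires):
    snap = make_snapshot(orders=[make_order("J01XX08", route="iv", indication=indication)])
    alert = evaluate_rule(rule(ruleset, "linezolid_indication"), snap, ruleset.drug_sets)
    assert (alert is not None) is fires
    if indication is None and alert:
        assert "indication undocumented" in alert.evidence["indication"]


# --------------------------------------------------------------------------
# DDI overrides


def test_ddi_override_fires_only_for_very_severe_with_both_active(ruleset):
    r = rule(ruleset, "ddi_xa_anticoagulant")
    orders = [make_order("B01AF01"), make_order("B01AB05")]
    fires = make_snapshot(orders=orders, overrides=[override("B01AF01", "B01AB05")])
    assert evaluate_rule(r, fires, ruleset.drug_sets) is not None
    # reversed pair order also matches
    reversed_pair = make_snapshot(orders=orders, overrides=[override("B01AB05", "B01AF01")])
    assert evaluate_rule(r, reversed_pair, ruleset.drug_sets) is not None
    merely_severe = make_snapshot(
        orders=orders, overrides=[override("B01AF01", "B01AB05", severity="severe", motivation="")]
    )
    assert evaluate_rule(r, merely_severe, ruleset.drug_sets) is None
    stopped = make_snapshot(
        orders=[make_order("B01AF01"),
                make_order("B01AB05", stop=NOON - dt.timedelta(hours=1))],
        overrides=[override("B01AF01", "B01AB05")],
    )
    assert evaluate_rule(r, stopped, ruleset.drug_sets) is None


# --------------------------------------------------------------------------
# sequential therapy


def test_sequential_therapy_auto_note(ruleset):
    snap = make_snapshot(gi=True, orders=[make_order("J01MA12", route="iv", name="levofloxacin")])
    note = detect_sequential_therapy(snap, ruleset.bioequivalence)
    assert note is not None
    assert note.switches[0]["oral_code"] == "J01MA12"
    assert "levofloxacin" in note.text


def test_sequential_requires_intact_absorption_and_table_entry(ruleset):
    no_gi = make_snapshot(gi=False, orders=[make_order("J01MA12", route="iv")])
    assert detect_sequential_therapy(no_gi, ruleset.bioequivalence) is None
    no_entry = make_snapshot(gi=True, orders=[make_order("J01DH02", route="iv")])
    assert detect_sequential_therapy(no_entry, ruleset.bioequivalence) is None
    oral_already = make_snapshot(gi=True, orders=[make_order("J01MA12", route="oral")])
    assert detect_sequential_therapy(oral_already, ruleset.bioequivalence) is None


# --------------------------------------------------------------------------
# population screening


def test_screen_population_contract(ruleset):
    empty = screen_population([], ruleset.rules, ruleset.drug_sets, ruleset.bioequivalence, DATE)
    assert empty == ([], [])

    two_rules = make_snapshot(
        patient_id="pA",
        labs=[lab("crcl_measured", 20.0), lab("inr", 5.0)],
        orders=[make_order("A10BA02"), make_order("B01AA03")],
    )
    alerts, notes = screen_population(
        [two_rules], ruleset.rules, ruleset.drug_sets, ruleset.bioequivalence, DATE
    )
    assert sorted(a.rule_id for a in alerts) == ["renal_metformin", "supratherapeutic_inr_vka"]
    assert notes == []

    with pytest.raises(ValueError, match="not on screening date"):
        screen_population(
            [make_snapshot(date=DATE + dt.timedelta(days=1))],
            ruleset.rules, ruleset.drug_sets, ruleset.bioequivalence, DATE,
        )


def test_screening_is_pure_and_deterministic(ruleset):
    snaps = [
        make_snapshot(patient_id="pB", labs=[lab("potassium", 6.0)], orders=[make_order("C09AA02")]),
        make_snapshot(patient_id="pA", labs=[lab("inr", 4.5)], orders=[make_order("B01AA03")]),
    ]
    first = screen_population(snaps, ruleset.rules, ruleset.drug_sets, ruleset.bioequivalence, DATE)
    second = screen_population(snaps, ruleset.rules, ruleset.drug_sets, ruleset.bioequivalence, DATE)
    assert first == second
    assert [a.patient_id for a in first[0]] == ["pA", "pB"]  # deterministic order


def test_conjunction_monotonicity(ruleset):
    """Dropping a conjunct can only widen the alerted set."""
    full = rule(ruleset, "hypokalemia_flucloxacillin")
    relaxed = full.model_copy(update={"criteria": full.criteria[:2]})  # drop drug_absent
    snaps = [
        make_snapshot(patient_id="s1", labs=[lab("potassium", 3.2)],
                      orders=[make_order("J01CF05"), make_order("A12BA01")]),
        make_snapshot(patient_id="s2", labs=[lab("potassium", 3.2)],
                      orders=[make_order("J01CF05")]),
        make_snapshot(patient_id="s3", labs=[lab("potassium", 4.2)],
                      orders=[make_order("J01CF05")]),
    ]
    fired_full = {s.patient_id for s in snaps if evaluate_rule(full, s, ruleset.drug_sets)}
    fired_relaxed = {s.patient_id for s in snaps if evaluate_rule(relaxed, s, ruleset.drug_sets)}
    assert fired_full <= fired_relaxed
    assert fired_relaxed == {"s1", "s2"}


def test_sequential_rules_never_reach_worklist(ruleset):
    snap = make_snapshot(gi=True, orders=[make_order("J01MA12", route="iv")])
    alerts, notes = screen_population(
        [snap], ruleset.rules, ruleset.drug_sets, ruleset.bioequivalence, DATE
    )
    assert all(a.category is not RuleCategory.sequential_therapy for a in alerts)
    assert len(notes) == 1
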