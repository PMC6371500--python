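"""Independent brute-force re-check of every shipped rule, working directly
on the generated census tables (pandas rows, hand-coded predicates) rather
than through the engine's snapshot/criterion machinery.  Used to verify
screening alert-for-alert."""

import datetime as dt

QTC_DRUGS = {"N05AD01", "J01MA12", "J01MA14", "A04AA01", "J02AC01", "C07AA07",
             "A03FA03", "N05BB01"}
BIOEQ_IV = {"J01MA12", "J01MA02", "J02AC01", "J01FF01", "J01XD01", "J01AA02", "N02BE01"}


def _noon(date):
    return dt.datetime.combine(date, dt.time(12, 0))


def _active_rows(orders, pid, noon):
    rows = []
    for _, r in orders[orders["patient_id"] == pid].iterrows():
        start = dt.datetime.fromisoformat(r["start"])
        stop = dt.datetime.fromisoformat(r["stop"]) if r["stop"] else None
        if start <= noon and (stop is None or noon < stop):
            rows.append(r)
    return rows


def _latest(labs, pid, analyte, noon, window_h):
    best_t, best_v = None, None
    for _, r in labs[(labs["patient_id"] == pid) & (labs["analyte"] == analyte)].iterrows():
        t = dt.datetime.fromisoformat(r["timestamp"])
        if t <= noon and t >= noon - dt.timedelta(hours=window_h):
            if best_t is None or t > best_t:
                best_t, best_v = t, float(r["value"])
    return best_t, best_v


def _latest_qtc(params, pid, noon, window_h=72):
    best_t, best_v = None, None
    for _, r in params[(params["patient_id"] == pid) & (params["kind"] == "qtc")].iterrows():
        t = dt.datetime.fromisoformat(r["timestamp"])
        if t <= noon and t >= noon - dt.timedelta(hours=window_h):
            if best_t is None or t > best_t:
                best_t, best_v = t, float(r["value"])
    return best_v


def _crcl(labs, patient, noon):
    t_meas, v_meas = _latest(labs, patient["patient_id"], "crcl_measured", noon, 168)
    t_scr, v_scr = _latest(labs, patient["patient_id"], "serum_creatinine", noon, 168)
    if t_meas is not None and (t_scr is None or t_meas >= t_scr):
        return v_meas
    if t_scr is None or not patient.get("sex") or not patient.get("weight_kg"):
        return v_meas
    age = int(patient["age"])
    if age < 18:
        return None
    crcl = (140 - age) * float(patient["weight_kg"]) / (72 * v_scr)
    return crcl * 0.85 if patient["sex"] == "female" else crcl


def _very_severe_pair(overrides, pid, set_a, set_b, active_codes, orders, noon):
    def member(code, prefixes, explicit):
        return code in explicit or any(code.startswith(p) for p in prefixes)

    for _, r in overrides[overrides["patient_id"] == pid].iterrows():
        if r["severity"] != "very_severe":
            continue
        a, b = r["drug_a"], r["drug_b"]
        pa, ea = set_a
        pb, eb = set_b
        match = (member(a, pa, ea) and member(b, pb, eb)) or (
            member(b, pa, ea) and member(a, pb, eb)
        )
        if match and a in active_codes and b in active_codes:
            return True
    return False


def brute_force_alerts(frames, date):
    """(patient_id, rule_id) pairs expected to alert, plus expected
    sequential-therapy patient ids."""
    noon = _noon(date)
    patients = frames.patients[frames.patients["snapshot_date"] == date.isoformat()]
    labs, params, orders, overrides = frames.labs, frames.params, frames.orders, frames.overrides
    # coerce numeric/string columns as read from CSV-like frames
    expected = set()
    seq_expected = set()
    for _, p in patients.iterrows():
        if str(p["admission_class"]) not in ("inpatient_non_icu", "day_care"):
            continue
        pid = p["patient_id"]
        active = _active_rows(orders, pid, noon)
        active_codes = {r["drug_code"] for r in active}

        def has(code):
            return code in active_codes

        def has_prefix(*prefixes):
            return any(any(c.startswith(px) for px in prefixes) for c in active_codes)

        crcl = _crcl(labs, p, noon)
        if crcl is not None and crcl < 30 and has("A10BA02"):
            expected.add((pid, "renal_metformin"))

        qtc = _latest_qtc(params, pid, noon)
        thr = 470 if p.get("sex") == "female" else 450
        if qtc is not None and qtc > thr and (active_codes & QTC_DRUGS):
            expected.add((pid, "qtc_prolonging_drug"))

        _, k = _latest(labs, pid, "potassium", noon, 72)
        if k is not None and k > 5.5 and has_prefix("C09A", "C09B"):
            expected.add((pid, "hyperkalemia_ace"))
        if (
            k is not None and k < 3.5 and has("J01CF05")
            and not has_prefix("A12BA") and not has("B05XA01")
        ):
            expected.add((pid, "hypokalemia_flucloxacillin"))

        _, inr = _latest(labs, pid, "inr", noon, 72)
        if inr is not None and inr > 4 and has_prefix("B01AA"):
            expected.add((pid, "supratherapeutic_inr_vka"))

        _, anc = _latest(labs, pid, "anc", noon, 72)
        if anc is not None and anc < 1.5 and has("N05AH02"):
            expected.add((pid, "neutropenia_clozapine"))

        for r in active:
            if r["drug_code"] == "J01DH02" and float(r["dose_mg"]) >= 2000 and float(r["frequency_hours"]) <= 8:
                expected.add((pid, "meropenem_high_dose"))
            if r["drug_code"] == "J01XB01" and float(r["dose_mg"]) >= 160 and float(r["frequency_hours"]) <= 8:
                expected.add((pid, "colistin_dose"))
        for code, rid, allowed in [
            ("J01XX08", "linezolid_indication", {"MRSA_INFECTION", "VRE_INFECTION"}),
            ("J01CA17", "temocillin_indication", {"ESBL_INFECTION", "UTI"}),
            ("J04AB02", "rifampicin_indication", {"TUBERCULOSIS", "FOREIGN_BODY_INFECTION"}),
        ]:
            for r in active:
                if r["drug_code"] == code and (not r["indication_code"] or r["indication_code"] not in allowed):
                    expected.add((pid, rid))
        for r in active:
            if r["route"] == "enteral_tube" and str(r["crushable"]).lower() in ("false", "0", "no"):
                expected.add((pid, "tube_non_crushable"))

        pair_rules = [
            ("ddi_valproate_carbapenem", (((), {"N03AG01"}), (("J01DH",), {"J01DH02"}))),
            ("ddi_xa_anticoagulant", ((("B01AF",), {"B01AF01", "B01AF02"}),
                                      (("B01AB",), {"B01AB05", "B01AB10"}))),
            ("ddi_qtc_antiarrhythmic", (((), QTC_DRUGS), (("C01B",), {"C01BD01"}))),
            ("ddi_antiarrhythmic_antipsychotic", ((("C01B",), {"C01BD01"}),
                                                  (("N05A",), {"N05AH02"}))),
        ]
        for rid, (set_a, set_b) in pair_rules:
            if _very_severe_pair(overrides, pid, set_a, set_b, active_codes, orders, noon):
                expected.add((pid, rid))

        if str(p["gi_absorption_intact"]).lower() in ("true", "1", "yes"):
            if any(r["route"] == "iv" and r["drug_code"] in BIOEQ_IV for r in active):
                seq_expected.add(pid)

    return expected, seq_expected
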