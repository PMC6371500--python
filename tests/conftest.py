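import datetime as dt

import pytest

from cma.io import load_ruleset
from cma.model import (
    ClinicalParameter,
    DDIOverrideEvent,
    LabResult,
    MedicationOrder,
    PatientSnapshot,
)

DATE = dt.date(2026, 3, 1)
NOON = dt.datetime.combine(DATE, dt.time(12, 0))
MORNING = dt.datetime.combine(DATE, dt.time(8, 0))


@pytest.fixture(scope="session")
def ruleset():
    return load_ruleset()


def make_order(drug_code, *, route="oral", dose=500.0, freq=12.0, start_days_ago=1,
               stop=None, crushable=True, indication=None, order_id=None, name=""):
    start = NOON - dt.timedelta(days=start_days_ago)
    return MedicationOrder(
        order_id=order_id or f"o-{drug_code}-{route}",
        drug_code=drug_code,
        drug_name=name,
        dose_mg=dose,
        frequency_hours=freq,
        route=route,
        start=start,
        stop=stop,
        crushable=crushable,
        indication_code=indication,
    )


def make_snapshot(*, patient_id="p1", age=60, sex="male", weight=72.0, ward="ED",
                  admission="inpatient_non_icu", gi=False, labs=(), params=(),
                  orders=(), overrides=(), date=DATE):
    return PatientSnapshot(
        patient_id=patient_id,
        snapshot_date=date,
        age=age,
        sex=sex,
        weight_kg=weight,
        ward=ward,
        admission_class=admission,
        gi_absorption_intact=gi,
        labs=list(labs),
        clinical_params=list(params),
        orders=list(orders),
        overrides=list(overrides),
    )


def lab(analyte, value, hours_before_noon=2.0):
    return LabResult(
        analyte=analyte, value=value, timestamp=NOON - dt.timedelta(hours=hours_before_noon)
    )


def qtc(value, hours_before_noon=2.0):
    return ClinicalParameter(
        kind="qtc", value=value, timestamp=NOON - dt.timedelta(hours=hours_before_noon)
    )


def override(a, b, severity="very_severe", motivation="benefit outweighs risk"):
    return DDIOverrideEvent(
        drug_a=a, drug_b=b, severity=severity, motivation=motivation,
        physician_id="md1", timestamp=MORNING,
    )
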