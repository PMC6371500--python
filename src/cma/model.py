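"""Domain types shared by all surveillance stages.

The screening pipeline consumes one :class:`PatientSnapshot` per patient per
day: the structured EHR state (demographics, active medication orders, recent
laboratory results, clinical parameters, and CDSS drug–drug-interaction
override events) as of the daily screening instant.  All laboratory values are
normalised to one canonical unit per analyte at ingestion so that rule
thresholds compare like with like.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
import re
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("cma")


class Analyte(str, enum.Enum):
    serum_creatinine = "serum_creatinine"
    potassium = "potassium"
    inr = "inr"
    anc = "anc"
    crcl_measured = "crcl_measured"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class AdmissionClass(str, enum.Enum):
    inpatient_non_icu = "inpatient_non_icu"
    day_care = "day_care"
    icu = "icu"
    discharged = "discharged"


class Route(str, enum.Enum):
    iv = "iv"
    oral = "oral"
    enteral_tube = "enteral_tube"
    other = "other"


class DDISeverity(str, enum.Enum):
    very_severe = "very_severe"
    severe = "severe"
    other = "other"


#: canonical unit per analyte, and accepted input units with conversion
#: factors (canonical = raw * factor).
CANONICAL_UNITS: dict[Analyte, str] = {
    Analyte.serum_creatinine: "mg/dL",
    Analyte.potassium: "mmol/L",
    Analyte.inr: "",
    Analyte.anc: "10^9/L",
    Analyte.crcl_measured: "mL/min",
}

_UNIT_FACTORS: dict[Analyte, dict[str, float]] = {
    Analyte.serum_creatinine: {
        "mg/dl": 1.0,
        # SI creatinine; 88.4 µmol/L per mg/dL
        "µmol/l": 1.0 / 88.4,
        "umol/l": 1.0 / 88.4,
        "μmol/l": 1.0 / 88.4,
    },
    Analyte.potassium: {"mmol/l": 1.0, "meq/l": 1.0},
    Analyte.inr: {"": 1.0, "ratio": 1.0, "inr": 1.0},
    Analyte.anc: {
        "10^9/l": 1.0,
        "g/l": 1.0,
        "10e9/l": 1.0,
        # counts per microlitre: 1500/µL = 1.5e9/L
        "cells/µl": 1e-3,
        "cells/ul": 1e-3,
        "cells/mm3": 1e-3,
        "/µl": 1e-3,
        "/ul": 1e-3,
    },
    Analyte.crcl_measured: {"ml/min": 1.0},
}


class UnitError(ValueError):
    """Raised when a lab value arrives in a unit unknown for its analyte."""


def normalize_lab(raw_value: float, raw_unit: str, analyte: Analyte | str) -> float:
    """Convert a raw laboratory value to the analyte's canonical unit.

    Canonical units: creatinine mg/dL, potassium mmol/L, INR dimensionless,
    ANC 10^9/L, CrCl mL/min.  Conversion is lossless for already-canonical
    input, hence idempotent.

    Raises
    ------
    UnitError
        If ``raw_unit`` is not a recognised unit for ``analyte``.
    """
    analyte = Analyte(analyte)
    factors = _UNIT_FACTORS[analyte]
    key = raw_unit.strip().lower()
    if key not in factors:
        raise UnitError(f"unknown unit {raw_unit!r} for analyte {analyte.value!r}")
    return float(raw_value) * factors[key]


_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")


class ATCError(ValueError):
    """Raised for syntactically invalid ATC codes."""


def _check_atc(code: str) -> str:
    if not _ATC_RE.match(code):
        raise ATCError(f"malformed ATC code {code!r}")
    return code


class DrugSet(BaseModel):
    """Named set of drugs encoded as ATC prefixes and/or explicit codes.

    Membership is prefix OR exact match; this is how rule files refer to drug
    classes ('VKA', 'ACE inhibitor', 'QTc-prolonging drugs') portably.
    """

    name: str
    atc_prefixes: list[str] = Field(default_factory=list)
    explicit_codes: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _non_empty(self) -> "DrugSet":
        if not self.atc_prefixes and not self.explicit_codes:
            raise ValueError(f"drug set {self.name!r} is empty")
        for c in self.atc_prefixes + self.explicit_codes:
            _check_atc(c)
        return self

    def __contains__(self, code: str) -> bool:
        return drug_in_set(code, self)


def drug_in_set(code: str, drug_set: DrugSet) -> bool:
    """True iff ``code`` starts with any of the set's prefixes or is listed
    explicitly.  Malformed codes are rejected rather than silently negative."""
    _check_atc(code)
    return code in drug_set.explicit_codes or any(
        code.startswith(p) for p in drug_set.atc_prefixes
    )


class LabResult(BaseModel):
    analyte: Analyte
    value: float  # canonical unit
    timestamp: dt.datetime

    @model_validator(mode="after")
    def _positive(self) -> "LabResult":
        if self.analyte in (Analyte.serum_creatinine, Analyte.potassium, Analyte.anc):
            if self.value <= 0:
                raise ValueError(f"{self.analyte.value} must be > 0, got {self.value}")
        return self

    @classmethod
    def from_raw(
        cls, analyte: Analyte | str, raw_value: float, raw_unit: str, timestamp: dt.datetime
    ) -> "LabResult":
        return cls(
            analyte=Analyte(analyte),
            value=normalize_lab(raw_value, raw_unit, analyte),
            timestamp=timestamp,
        )


class ClinicalParameter(BaseModel):
    """A bedside clinical measurement; currently the heart-rate-corrected QT
    interval (QTc, milliseconds).  Physiologically impossible values are
    rejected at ingestion (200–800 ms)."""

    kind: str = "qtc"
    value: float
    timestamp: dt.datetime

    @model_validator(mode="after")
    def _bounded(self) -> "ClinicalParameter":
        if self.kind == "qtc" and not (200.0 <= self.value <= 800.0):
            raise ValueError(f"QTc {self.value} ms outside physiologic bounds 200-800 ms")
        return self


class MedicationOrder(BaseModel):
    order_id: str
    drug_code: str  # ATC
    drug_name: str = ""
    dose_mg: float  # per administration, normalised to mg
    frequency_hours: float  # dosing interval
    route: Route
    start: dt.datetime
    stop: Optional[dt.datetime] = None  # open-ended when absent
    crushable: bool = True
    indication_code: Optional[str] = None

    @model_validator(mode="after")
    def _valid(self) -> "MedicationOrder":
        _check_atc(self.drug_code)
        if self.dose_mg <= 0:
            raise ValueError(f"order {self.order_id}: dose must be > 0")
        if self.frequency_hours <= 0:
            raise ValueError(f"order {self.order_id}: frequency_hours must be > 0")
        if self.stop is not None and not self.start < self.stop:
            raise ValueError(f"order {self.order_id}: start must precede stop")
        return self

    def active_at(self, instant: dt.datetime) -> bool:
        """Half-open activity interval [start, stop): an order stopping at the
        screening instant is already inactive, so switch days are not
        double-counted."""
        if instant < self.start:
            return False
        return self.stop is None or instant < self.stop


class DDIOverrideEvent(BaseModel):
    """A physician override of a CDSS drug–drug-interaction alert.  Only very
    severe interactions require an override, and those require a motivation."""

    drug_a: str
    drug_b: str
    severity: DDISeverity
    motivation: str = ""
    physician_id: str = ""
    timestamp: dt.datetime

    @model_validator(mode="after")
    def _motivated(self) -> "DDIOverrideEvent":
        _check_atc(self.drug_a)
        _check_atc(self.drug_b)
        if self.severity is DDISeverity.very_severe and not self.motivation.strip():
            raise ValueError("very severe DDI override requires a motivation")
        return self


#: daily screening time-of-day.  Screening "daily at 12 am" is read as noon —
#: a midnight run could not see same-day morning labs; configurable.
SCREENING_TIME = dt.time(12, 0)


class PatientSnapshot(BaseModel):
    """One patient-day of structured EHR state.

    Only non-critically-ill inpatients and day-care admissions are screened;
    ICU and discharged snapshots are accepted at ingestion but skipped by the
    screening pass (ICU prescribing lives in a separate system).
    """

    patient_id: str
    snapshot_date: dt.date
    age: int = Field(ge=0)
    sex: Optional[Sex] = None
    weight_kg: Optional[float] = Field(default=None, gt=0)
    ward: str = ""
    admission_class: AdmissionClass = AdmissionClass.inpatient_non_icu
    gi_absorption_intact: bool = False
    labs: list[LabResult] = Field(default_factory=list)
    clinical_params: list[ClinicalParameter] = Field(default_factory=list)
    orders: list[MedicationOrder] = Field(default_factory=list)
    overrides: list[DDIOverrideEvent] = Field(default_factory=list)

    @field_validator("snapshot_date", mode="before")
    @classmethod
    def _coerce_date(cls, v):
        if isinstance(v, str):
            return dt.date.fromisoformat(v)
        return v

    @property
    def screening_instant(self) -> dt.datetime:
        return dt.datetime.combine(self.snapshot_date, SCREENING_TIME)

    @property
    def eligible(self) -> bool:
        return self.admission_class in (
            AdmissionClass.inpatient_non_icu,
            AdmissionClass.day_care,
        )

    def latest_lab(
        self, analyte: Analyte, max_age_hours: Optional[float] = None
    ) -> Optional[LabResult]:
        """Most recent result for ``analyte`` at or before the screening
        instant, optionally restricted to a staleness window."""
        instant = self.screening_instant
        candidates = [
            lab
            for lab in self.labs
            if lab.analyte is analyte and lab.timestamp <= instant
        ]
        if max_age_hours is not None:
            horizon = instant - dt.timedelta(hours=max_age_hours)
            candidates = [lab for lab in candidates if lab.timestamp >= horizon]
        return max(candidates, key=lambda lab: lab.timestamp, default=None)

    def latest_param(
        self, kind: str = "qtc", max_age_hours: Optional[float] = None
    ) -> Optional[ClinicalParameter]:
        instant = self.screening_instant
        candidates = [
            p for p in self.clinical_params if p.kind == kind and p.timestamp <= instant
        ]
        if max_age_hours is not None:
            horizon = instant - dt.timedelta(hours=max_age_hours)
            candidates = [p for p in candidates if p.timestamp >= horizon]
        return max(candidates, key=lambda p: p.timestamp, default=None)

    def active_orders(self, instant: Optional[dt.datetime] = None) -> list[MedicationOrder]:
        instant = instant or self.screening_instant
        return [o for o in self.orders if o.active_at(instant)]
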