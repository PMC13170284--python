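"""Statin-eligibility determination and encounter outcome classification.

Eligibility pools four guideline-based indications into a single
"statin-eligible" category:

1. age 20-75 with LDL >= 190 mg/dL and type 2 diabetes (as printed in the
   study's inclusion table the two are required together; the usual
   guideline reading — LDL >= 190 alone — is available via
   ``ldl190_requires_diabetes=False``);
2. age 40-75 with type 2 diabetes and a history of MI or stroke;
3. age 40-75 with an estimated 10-year ASCVD risk >= 7.5% under the 2013
   ACC/AHA Pooled Cohort Equations (PCE);
4. age 20-75 with a history of MI or stroke.

Exclusions (pregnancy, statin allergy/contraindication, hepatitis,
cirrhosis, ESRD, CKD) dominate every inclusion.  Patients missing any
PCE input within the 3-year lookback are ineligible with reason
``missing_risk_inputs``.  Type 2 diabetes is the disjunction of a
diagnosis-code flag and HbA1c >= 6.5% on the latest draw.

The PCE coefficient tables are embedded as versioned package data
(``data/pce_coefficients.json``) and can be overridden, or bypassed
entirely by supplying an externally computed risk column.
"""

from __future__ import annotations

import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, MissingDataError

RISK_THRESHOLD = 0.075
LOOKBACK_DAYS = 3 * 365
HBA1C_DIABETES_THRESHOLD = 6.5

INDICATIONS = ("ldl190_dm", "dm_with_ascvd_history", "risk_ge_7.5", "ascvd_history", "none")


def _load_json(name: str) -> dict:
    ref = importlib.resources.files("cogload.data").joinpath(name)
    return json.loads(ref.read_text())


def load_pce_coefficients() -> dict:
    """The embedded 2013 PCE coefficient tables (overridable copy)."""
    return _load_json("pce_coefficients.json")


def load_code_sets() -> dict:
    """Editable default code sets (synthetic stand-ins for site lists)."""
    return _load_json("code_sets_synthetic.json")


@dataclass
class PatientRecord:
    """One patient's inputs to eligibility assessment.

    Lab values are in mg/dL, systolic blood pressure in mmHg, HbA1c in
    percent.  ``measurement_dates`` may record a per-variable measurement
    date (any of ``lipids``, ``hba1c``, ``sbp``, ``smoking``); variables
    without a recorded date are treated as current.
    """

    age: float
    sex: str  # "male" | "female"
    race_ethnicity: str = "White"
    systolic_bp: Optional[float] = None
    total_cholesterol: Optional[float] = None
    hdl: Optional[float] = None
    ldl: Optional[float] = None
    hba1c: Optional[float] = None
    bp_treated: bool = False
    diabetes_flag: bool = False
    smoking_flag: Optional[bool] = None
    prior_mi_or_stroke_flag: bool = False
    pregnancy_flag: bool = False
    statin_allergy_or_contraindication_flag: bool = False
    hepatitis_flag: bool = False
    cirrhosis_flag: bool = False
    esrd_flag: bool = False
    ckd_flag: bool = False
    insurance_class: str = "commercial"
    n_active_diagnoses: int = 0
    comorbidity_index: int = 0
    measurement_dates: dict = field(default_factory=dict)
    encounter_date: Optional[date] = None

    def __post_init__(self):
        for fld in ("systolic_bp", "total_cholesterol", "hdl", "ldl"):
            val = getattr(self, fld)
            if val is not None and not val > 0:
                raise DomainError(f"{fld} must be strictly positive, got {val}")
        if self.hba1c is not None and not (3.0 < self.hba1c < 20.0):
            raise DomainError(f"hba1c must lie in (3, 20), got {self.hba1c}")

    @property
    def has_diabetes(self) -> bool:
        """Code-set flag OR latest HbA1c at/above the diabetes threshold."""
        return bool(self.diabetes_flag) or (
            self.hba1c is not None and self.hba1c >= HBA1C_DIABETES_THRESHOLD
        )


@dataclass(frozen=True)
class EligibilityResult:
    risk_10yr: Optional[float]
    eligible: bool
    indication: str
    exclusion_reason: Optional[str] = None


def _pce_group(sex: str, race_ethnicity: str) -> str:
    # Categories outside the equation's published strata use the
    # non-Black ("white") coefficient set, per common calculator practice.
    race = "black" if str(race_ethnicity).lower() in ("black", "black/african american") else "white"
    sex = str(sex).lower()
    if sex not in ("male", "female"):
        raise DomainError(f"sex must be 'male' or 'female', got {sex!r}")
    return f"{race}_{sex}"


def ascvd_risk_2013(
    record: PatientRecord, coefficients: dict | None = None
) -> float:
    """10-year ASCVD risk under the 2013 Pooled Cohort Equations.

    Parameters
    ----------
    record
        Must carry age, sex, systolic BP (with treatment flag), total
        cholesterol, HDL, diabetes status and smoking status.
    coefficients
        Optional override of the embedded coefficient tables (same JSON
        schema).

    Returns
    -------
    float in [0, 1].
    """
    tables = coefficients or load_pce_coefficients()
    required = {
        "age": record.age,
        "sex": record.sex,
        "systolic_bp": record.systolic_bp,
        "total_cholesterol": record.total_cholesterol,
        "hdl": record.hdl,
        "smoking_flag": record.smoking_flag,
    }
    for name, val in required.items():
        if val is None:
            raise MissingDataError(f"PCE input {name!r} is missing")
    if not (20.0 <= record.age <= 79.0):
        raise DomainError(f"age {record.age} outside the supported 20-79 range")

    group = tables["groups"][_pce_group(record.sex, record.race_ethnicity)]
    coefs = group["coefficients"]
    la = math.log(record.age)
    ltc = math.log(record.total_cholesterol)
    lhdl = math.log(record.hdl)
    lsbp = math.log(record.systolic_bp)
    treated = bool(record.bp_treated)
    smoker = float(bool(record.smoking_flag))
    dm = float(record.has_diabetes)
    terms = {
        "ln_age": la,
        "ln_age_sq": la * la,
        "ln_tc": ltc,
        "ln_age_ln_tc": la * ltc,
        "ln_hdl": lhdl,
        "ln_age_ln_hdl": la * lhdl,
        "ln_sbp_treated": lsbp if treated else 0.0,
        "ln_age_ln_sbp_treated": la * lsbp if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else lsbp,
        "ln_age_ln_sbp_untreated": 0.0 if treated else la * lsbp,
        "smoker": smoker,
        "ln_age_smoker": la * smoker,
        "diabetes": dm,
    }
    lp = sum(coef * terms[key] for key, coef in coefs.items())
    risk = 1.0 - group["baseline_survival"] ** math.exp(lp - group["mean_lp"])
    return float(min(max(risk, 0.0), 1.0))


def _within_lookback(record: PatientRecord, variable: str, lookback_days: int) -> bool:
    when = record.measurement_dates.get(variable)
    if when is None:
        return True  # undated measurements are treated as current
    ref = record.encounter_date or date.today()
    if isinstance(when, datetime):
        when = when.date()
    if isinstance(ref, datetime):
        ref = ref.date()
    return (ref - when).days <= lookback_days


def assess_eligibility(
    record: PatientRecord,
    lookback_days: int = LOOKBACK_DAYS,
    ldl190_requires_diabetes: bool = True,
    risk_override: Optional[float] = None,
    coefficients: dict | None = None,
) -> EligibilityResult:
    """Apply the pooled inclusion rules and all exclusions to one patient.

    Exclusions dominate; missing or stale (beyond the lookback window)
    risk-equation inputs make the patient ineligible with reason
    ``missing_risk_inputs``.  ``risk_override`` injects an externally
    computed 10-year risk instead of evaluating the PCE.
    """
    for reason, flagged in (
        ("pregnancy", record.pregnancy_flag),
        ("statin_allergy_or_contraindication", record.statin_allergy_or_contraindication_flag),
        ("hepatitis", record.hepatitis_flag),
        ("cirrhosis", record.cirrhosis_flag),
        ("esrd", record.esrd_flag),
        ("ckd", record.ckd_flag),
    ):
        if flagged:
            return EligibilityResult(None, False, "none", reason)

    # PCE inputs must exist and be dated within the lookback window.
    risk: Optional[float] = None
    if risk_override is not None:
        risk = float(risk_override)
    else:
        inputs_present = all(
            v is not None
            for v in (
                record.systolic_bp,
                record.total_cholesterol,
                record.hdl,
                record.ldl,
                record.smoking_flag,
            )
        )
        inputs_fresh = all(
            _within_lookback(record, var, lookback_days)
            for var in ("lipids", "hba1c", "sbp", "smoking")
        )
        if not (inputs_present and inputs_fresh):
            return EligibilityResult(None, False, "none", "missing_risk_inputs")
        try:
            risk = ascvd_risk_2013(record, coefficients=coefficients)
        except (MissingDataError, DomainError):
            return EligibilityResult(None, False, "none", "missing_risk_inputs")

    age, dm = record.age, record.has_diabetes
    history = record.prior_mi_or_stroke_flag
    if (
        20.0 <= age <= 75.0
        and record.ldl is not None
        and record.ldl >= 190.0
        and (dm or not ldl190_requires_diabetes)
    ):
        return EligibilityResult(risk, True, "ldl190_dm")
    if 40.0 <= age <= 75.0 and dm and history:
        return EligibilityResult(risk, True, "dm_with_ascvd_history")
    if 40.0 <= age <= 75.0 and risk is not None and risk >= RISK_THRESHOLD:
        return EligibilityResult(risk, True, "risk_ge_7.5")
    if 20.0 <= age <= 75.0 and history:
        return EligibilityResult(risk, True, "ascvd_history")
    return EligibilityResult(risk, False, "none")


@dataclass(frozen=True)
class EncounterOutcome:
    encounter_id: object
    initiated: bool
    order_timestamp: Optional[pd.Timestamp] = None

    def __post_init__(self):
        if self.initiated != (self.order_timestamp is not None):
            raise ValueError("initiated must hold exactly when an order timestamp is present")


def classify_outcome(
    encounter_id,
    orders: pd.DataFrame,
    encounter_window: tuple,
    statin_codes=None,
    segments=None,
) -> EncounterOutcome:
    """Classify one encounter as initiated vs not prescribed.

    Initiated means at least one statin order documented during the
    encounter window (first event time through last active-segment end);
    the earliest such timestamp is recorded.  Orders falling inside the
    window but outside every active segment are counted with a warning.

    Parameters
    ----------
    encounter_id
        CSN to classify.
    orders
        Medication-order table with columns ``csn``, ``medication``,
        ``order_time``.
    encounter_window
        (start, end) timestamps of the encounter.
    statin_codes
        Iterable of statin medication names/codes (defaults to the
        embedded code set); matching is case-insensitive substring-free
        equality.
    segments
        Optional iterable of :class:`~cogload.metrics.ActiveSegment` (or
        (start, end) pairs) used only for the out-of-segment warning.
    """
    if statin_codes is None:
        statin_codes = load_code_sets()["statin_medications"]
    codes = {str(c).lower() for c in statin_codes}
    start, end = (pd.Timestamp(encounter_window[0]), pd.Timestamp(encounter_window[1]))
    sub = orders[orders["csn"] == encounter_id]
    times = []
    for _, row in sub.iterrows():
        if str(row["medication"]).lower() not in codes:
            continue
        ts = pd.Timestamp(row["order_time"])
        if pd.isna(ts) or not (start <= ts <= end):
            continue
        if segments is not None:
            inside = any(
                (pd.Timestamp(getattr(s, "start", s[0])) <= ts <= pd.Timestamp(getattr(s, "end", s[1])))
                for s in segments
            )
            if not inside:
                warnings.warn(
                    f"statin order at {ts} for encounter {encounter_id!r} lies outside "
                    "every active segment; counted anyway"
                )
        times.append(ts)
    if not times:
        return EncounterOutcome(encounter_id, False, None)
    return EncounterOutcome(encounter_id, True, min(times))


def eligibility_frame(
    patients: pd.DataFrame,
    lookback_days: int = LOOKBACK_DAYS,
    ldl190_requires_diabetes: bool = True,
) -> pd.DataFrame:
    """Vectorised convenience wrapper: assess a whole patient table.

    Expects the column layout of :func:`cogload.simulate.simulate_patients`;
    returns one row per patient with ``risk_10yr``, ``eligible``,
    ``indication`` and ``exclusion_reason``.
    """
    results = []
    for _, row in patients.iterrows():
        record = PatientRecord(
            age=float(row["age"]),
            sex=row["sex"],
            race_ethnicity=row["race_ethnicity"],
            systolic_bp=float(row["systolic_bp"]),
            total_cholesterol=float(row["total_cholesterol"]),
            hdl=float(row["hdl"]),
            ldl=float(row["ldl"]),
            hba1c=float(row["hba1c"]),
            bp_treated=bool(row.get("bp_treated", False)),
            diabetes_flag=bool(row["diabetes_dx_flag"]),
            smoking_flag=bool(row["smoking_flag"]),
            prior_mi_or_stroke_flag=bool(row["prior_ascvd_flag"]),
            pregnancy_flag=bool(row["pregnancy_flag"]),
            statin_allergy_or_contraindication_flag=bool(row["statin_allergy_flag"]),
            hepatitis_flag=bool(row["hepatitis_flag"]),
            cirrhosis_flag=bool(row["cirrhosis_flag"]),
            esrd_flag=bool(row["esrd_flag"]),
            ckd_flag=bool(row["ckd_flag"]),
            insurance_class=row["insurance_class"],
            n_active_diagnoses=int(row["n_active_diagnoses"]),
            comorbidity_index=int(row["elixhauser"]),
            measurement_dates={
                "lipids": (pd.Timestamp(row["encounter_date"]) - pd.Timedelta(days=int(row["lipid_days_since"]))).date(),
                "hba1c": (pd.Timestamp(row["encounter_date"]) - pd.Timedelta(days=int(row["hba1c_days_since"]))).date(),
                "sbp": (pd.Timestamp(row["encounter_date"]) - pd.Timedelta(days=int(row["bp_days_since"]))).date(),
                "smoking": (pd.Timestamp(row["encounter_date"]) - pd.Timedelta(days=int(row["smoking_days_since"]))).date(),
            },
            encounter_date=pd.Timestamp(row["encounter_date"]).date(),
        )
        res = assess_eligibility(
            record,
            lookback_days=lookback_days,
            ldl190_requires_diabetes=ldl190_requires_diabetes,
        )
        results.append(
            {
                "patient_id": row["patient_id"],
                "risk_10yr": res.risk_10yr,
                "eligible": res.eligible,
                "indication": res.indication,
                "exclusion_reason": res.exclusion_reason,
            }
        )
    return pd.DataFrame(results)
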