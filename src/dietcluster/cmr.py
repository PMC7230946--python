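"""Cardiometabolic-risk (CMR) case/control classification.

A participant is a CMR case when at least three of five criteria hold:

* central adiposity — waist circumference >= 94 cm (men) / >= 80 cm (women);
* dyslipidemia — HDL < 1.0 mmol/L (men) / < 1.3 mmol/L (women), and/or
  non-HDL cholesterol >= 4.0 mmol/L, and/or lipid-lowering medication;
* elevated blood pressure — systolic >= 130 mmHg and/or diastolic >= 85
  mmHg and/or antihypertensive medication;
* inflammation — high-sensitivity CRP in [3, 10) mg/L (values of 10 mg/L
  or more indicate acute infection and do not qualify);
* impaired glucose control — HbA1c >= 5.7 % and/or glucose-lowering
  medication.

The glucose criterion alone doubles as the sensitivity outcome.  All
boundaries are applied exactly as written above (inclusive `>=`, exclusive
`<`).  Missing required fields make the outcome undefined for that
participant, which upstream maps to the incomplete-outcome exclusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError

CRITERIA = ("adiposity", "dyslipidemia", "blood_pressure", "inflammation", "glucose")

#: Biomarker / flag columns required to evaluate the five criteria.
REQUIRED_FIELDS = (
    "sex",
    "waist_cm",
    "hdl_mmol_l",
    "non_hdl_mmol_l",
    "sbp_mmhg",
    "dbp_mmhg",
    "crp_mg_l",
    "hba1c_pct",
    "meds_lipid",
    "meds_bp",
    "meds_glucose",
)

CUTOFFS = {
    "waist_male": 94.0,
    "waist_female": 80.0,
    "hdl_male": 1.0,
    "hdl_female": 1.3,
    "non_hdl": 4.0,
    "sbp": 130.0,
    "dbp": 85.0,
    "crp_low": 3.0,
    "crp_high": 10.0,
    "hba1c": 5.7,
}

CASE_THRESHOLD = 3


def _require(profiles: pd.DataFrame) -> None:
    missing = set(REQUIRED_FIELDS) - set(profiles.columns)
    if missing:
        raise InputError(f"profiles lack required fields: {sorted(missing)}")
    sexes = set(profiles["sex"].dropna().unique())
    if not sexes <= {"male", "female"}:
        raise InputError(f"sex must be 'male'/'female', got {sorted(sexes)}")


def evaluate_criteria(profiles: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the five CMR criteria for every row of ``profiles``.

    Returns a boolean DataFrame with columns :data:`CRITERIA`.  Rows with
    any missing required field get ``pd.NA`` in every criterion column.
    """
    _require(profiles)
    male = profiles["sex"] == "male"

    waist_cut = np.where(male, CUTOFFS["waist_male"], CUTOFFS["waist_female"])
    hdl_cut = np.where(male, CUTOFFS["hdl_male"], CUTOFFS["hdl_female"])

    crit = pd.DataFrame(index=profiles.index)
    crit["adiposity"] = profiles["waist_cm"] >= waist_cut
    crit["dyslipidemia"] = (
        (profiles["hdl_mmol_l"] < hdl_cut)
        | (profiles["non_hdl_mmol_l"] >= CUTOFFS["non_hdl"])
        | profiles["meds_lipid"].astype(bool)
    )
    crit["blood_pressure"] = (
        (profiles["sbp_mmhg"] >= CUTOFFS["sbp"])
        | (profiles["dbp_mmhg"] >= CUTOFFS["dbp"])
        | profiles["meds_bp"].astype(bool)
    )
    crit["inflammation"] = (profiles["crp_mg_l"] >= CUTOFFS["crp_low"]) & (
        profiles["crp_mg_l"] < CUTOFFS["crp_high"]
    )
    crit["glucose"] = (profiles["hba1c_pct"] >= CUTOFFS["hba1c"]) | profiles[
        "meds_glucose"
    ].astype(bool)

    incomplete = profiles[list(REQUIRED_FIELDS)].isna().any(axis=1)
    crit = crit.astype("boolean")
    crit[incomplete] = pd.NA
    return crit


def classify_cmr(criteria: pd.DataFrame, threshold: int = CASE_THRESHOLD) -> pd.Series:
    """Case/control label from the five criterion booleans: case iff
    the number of criteria met is at least ``threshold``."""
    if list(criteria.columns) != list(CRITERIA):
        criteria = criteria[list(CRITERIA)]
    counts = criteria.sum(axis=1)
    label = (counts >= threshold).astype("boolean")
    label[criteria.isna().any(axis=1)] = pd.NA
    return label


def glucose_only_outcome(profiles: pd.DataFrame) -> pd.Series:
    """Sensitivity outcome: impaired glucose control only."""
    _require(profiles)
    out = (profiles["hba1c_pct"] >= CUTOFFS["hba1c"]) | profiles["meds_glucose"].astype(bool)
    out = out.astype("boolean")
    out[profiles[["hba1c_pct", "meds_glucose"]].isna().any(axis=1)] = pd.NA
    return out


def outcome_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-participant criteria, composite case label and glucose-only label."""
    crit = evaluate_criteria(profiles)
    out = crit.copy()
    out["case"] = classify_cmr(crit)
    out["glucose_only_case"] = glucose_only_outcome(profiles)
    return out
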