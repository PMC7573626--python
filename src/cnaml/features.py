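"""Shared covariate encoding for hazard models and the cohort generator.

The supported covariate names (used both by the generator's true effects
and by the fitted transition models, so that simulation truth and
estimation speak the same language):

* ``age_c``      — age in years centered at 49;
* ``sex_female`` — 1 for female, 0 for male;
* ``log10_wcc``  — log10 of the presenting white cell count (x10^9/L),
  floored at 0.1 to keep the transform finite;
* ``cat2`` .. ``cat5`` — genotype-category indicators (Category 1 is the
  reference level);
* ``hsct``       — allogeneic HSCT at CR1, as a time-fixed indicator.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .genotype import classify_patient
from .schema import Cohort, PatientRecord

AGE_CENTER = 49.0
SUPPORTED_COVARIATES = (
    "age_c", "sex_female", "log10_wcc", "cat2", "cat3", "cat4", "cat5", "hsct",
)

DEFAULT_COVARIATES = list(SUPPORTED_COVARIATES)


def check_covariate_names(names) -> None:
    unknown = [n for n in names if n not in SUPPORTED_COVARIATES]
    if unknown:
        raise ValueError(
            f"unknown covariate name(s) {unknown}; supported: {list(SUPPORTED_COVARIATES)}"
        )


def covariate_value(patient: PatientRecord, name: str, category: int | None = None) -> float:
    if name == "age_c":
        return patient.covariates.age - AGE_CENTER
    if name == "sex_female":
        return 1.0 if patient.covariates.sex == "female" else 0.0
    if name == "log10_wcc":
        return math.log10(max(patient.covariates.wcc, 0.1))
    if name.startswith("cat"):
        if category is None:
            category = classify_patient(patient.mutations).category
        return 1.0 if category == int(name[3]) else 0.0
    if name == "hsct":
        return 1.0 if patient.history.hsct_time is not None else 0.0
    raise ValueError(f"unknown covariate {name!r}")


def covariate_frame(
    cohort: Cohort, names=DEFAULT_COVARIATES, hsct_override: dict[str, float] | None = None
) -> pd.DataFrame:
    """Design matrix (patients x covariates), indexed by patient_id.

    ``hsct_override`` lets callers evaluate counterfactual strategies by
    forcing the HSCT indicator per patient.
    """
    check_covariate_names(names)
    rows = []
    for p in cohort:
        category = classify_patient(p.mutations).category
        row = {n: covariate_value(p, n, category) for n in names}
        if hsct_override is not None and "hsct" in names and p.patient_id in hsct_override:
            row["hsct"] = hsct_override[p.patient_id]
        rows.append(row)
    return pd.DataFrame(rows, index=[p.patient_id for p in cohort], columns=list(names))
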