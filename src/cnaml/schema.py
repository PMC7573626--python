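"""Domain types and tabular I/O for CN-AML cohorts.

A cohort is exchanged as two delimited text tables:

* a clinical table, one row per patient, holding demographics, induction
  details and the event history (all times in months from diagnosis);
* a mutation table, one row per mutation call (patient_id, gene, subtype,
  vaf).  Patients absent from the mutation table are all-wild-type.

Validation is total: every invariant declared on the types below is
enforced by :func:`read_cohort` and by :func:`validate_patient`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "MutationCall",
    "ClinicalCovariates",
    "EventHistory",
    "PatientRecord",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "validate_patient",
    "maf_to_mutation_table",
]

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "wcc", "dauno_dose", "regimen",
    "induction_given", "cr1_time", "cr1_via_salvage", "relapse_time",
    "hsct_time", "death_time", "death_context", "last_followup",
]
MUTATION_COLUMNS = ["patient_id", "gene", "subtype", "vaf"]

SEXES = {"male", "female"}
DAUNO_DOSES = {"60", "90", "other", "none"}
DEATH_CONTEXTS = {"TRM_in_remission", "death_in_relapse", "death_refractory", "none"}


class SchemaError(ValueError):
    """A table is missing a required column or has an unparseable field."""


class ValidationError(ValueError):
    """A record violates a declared invariant."""


@dataclass(frozen=True)
class MutationCall:
    """One gene-level mutation call.

    ``subtype`` is a free-text variant label ("ITD", "TKD-D835", "R882",
    "typeA", "R132H", "biallelic", ...); ``vaf`` is the mutant-read
    fraction in [0, 1].  A gene may carry several distinct calls.
    """

    patient_id: str
    gene: str
    subtype: str
    vaf: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError(f"patient {self.patient_id!r}: gene symbol is empty")
        if not (0.0 <= self.vaf <= 1.0) or not math.isfinite(self.vaf):
            raise ValidationError(
                f"patient {self.patient_id!r}, gene {self.gene}: "
                f"vaf {self.vaf!r} violates 0 ≤ vaf ≤ 1"
            )


@dataclass(frozen=True)
class ClinicalCovariates:
    """Presentation covariates.

    ``age`` in years and ``wcc`` (presenting white cell count, x10^9/L)
    are continuous; ``dauno_dose`` is the daunorubicin dose stratum
    {"60", "90", "other", "none"} in mg/m2.
    """

    age: float
    sex: str
    wcc: float
    dauno_dose: str
    regimen: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age >= 0):
            raise ValidationError(f"age {self.age!r} must be finite and non-negative")
        if not (math.isfinite(self.wcc) and self.wcc >= 0):
            raise ValidationError(f"wcc {self.wcc!r} must be finite and non-negative")
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {sorted(SEXES)}")
        if self.dauno_dose not in DAUNO_DOSES:
            raise ValidationError(f"dauno_dose {self.dauno_dose!r} not in {sorted(DAUNO_DOSES)}")


@dataclass(frozen=True)
class EventHistory:
    """Post-diagnosis event history, times in months from diagnosis.

    Absent events are ``None``.  ``death_context`` distinguishes
    treatment-related mortality in remission, death in relapse and death
    without ever reaching remission.
    """

    induction_given: bool
    cr1_time: Optional[float]
    cr1_via_salvage: bool
    relapse_time: Optional[float]
    hsct_time: Optional[float]
    death_time: Optional[float]
    death_context: str
    last_followup: float


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    covariates: ClinicalCovariates
    mutations: tuple[MutationCall, ...]
    history: EventHistory

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations", tuple(self.mutations))


@dataclass(frozen=True)
class Cohort:
    """A list of validated patient records with provenance metadata."""

    patients: tuple[PatientRecord, ...]
    provenance: str = "imported"
    config_hash: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def subset(self, keep) -> "Cohort":
        return replace(self, patients=tuple(p for p in self.patients if keep(p)))


def validate_patient(patient: PatientRecord) -> None:
    """Enforce every EventHistory invariant; raise ValidationError naming
    the patient and the violated rule."""
    h = patient.history
    pid = patient.patient_id

    def bad(rule: str) -> ValidationError:
        return ValidationError(f"patient {pid!r}: {rule}")

    if not (math.isfinite(h.last_followup) and h.last_followup >= 0):
        raise bad("last_followup must be finite and >= 0")
    for name in ("cr1_time", "relapse_time", "hsct_time"):
        t = getattr(h, name)
        if t is not None and not (0 <= t <= h.last_followup):
            raise bad(f"{name}={t} must lie in [0, last_followup={h.last_followup}]")
    if h.death_time is not None and h.death_time != h.last_followup:
        raise bad(f"death_time={h.death_time} must equal last_followup={h.last_followup}")
    if h.relapse_time is not None:
        if h.cr1_time is None:
            raise bad("relapse_time present requires cr1_time present")
        if not h.relapse_time > h.cr1_time:
            raise bad(f"relapse_time={h.relapse_time} must exceed cr1_time={h.cr1_time}")
    if h.death_context not in DEATH_CONTEXTS:
        raise bad(f"death_context {h.death_context!r} not in {sorted(DEATH_CONTEXTS)}")
    if (h.death_context != "none") != (h.death_time is not None):
        raise bad("death_context != 'none' iff death_time present")
    if h.hsct_time is not None:
        if h.cr1_time is None:
            raise bad("hsct_time present requires cr1_time present (HSCT at CR1 only)")
        if h.hsct_time < h.cr1_time:
            raise bad(f"hsct_time={h.hsct_time} must be >= cr1_time={h.cr1_time}")


# ---------------------------------------------------------------------------
# tabular I/O


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "yes"}


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_cohort(clinical_path, mutations_path) -> Cohort:
    """Read and validate a cohort from its clinical and mutation tables.

    TSV or CSV is autodetected from the file extension.  Gene symbols are
    upper-cased on ingest; subtype labels are case-preserved.  Mutation
    rows whose patient_id does not appear in the clinical table are an
    error; clinical patients without mutation rows are all-wild-type.
    """
    clinical_path, mutations_path = Path(clinical_path), Path(mutations_path)
    clin = pd.read_csv(clinical_path, sep=_sep_for(clinical_path),
                       dtype={"patient_id": str}, float_precision="round_trip")
    muts = pd.read_csv(mutations_path, sep=_sep_for(mutations_path),
                       dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(clin, CLINICAL_COLUMNS, clinical_path)
    _require_columns(muts, MUTATION_COLUMNS, mutations_path)

    by_patient: dict[str, list[MutationCall]] = {}
    for row in muts.itertuples(index=False):
        call = MutationCall(
            patient_id=str(row.patient_id),
            gene=str(row.gene).upper(),
            subtype="" if pd.isna(row.subtype) else str(row.subtype),
            vaf=float(row.vaf),
        )
        by_patient.setdefault(call.patient_id, []).append(call)

    known_ids = set(clin["patient_id"].astype(str))
    unknown = sorted(set(by_patient) - known_ids)
    if unknown:
        raise ValidationError(f"mutation table references unknown patient_id(s): {unknown}")

    patients = []
    for row in clin.itertuples(index=False):
        pid = str(row.patient_id)
        cov = ClinicalCovariates(
            age=float(row.age),
            sex=str(row.sex),
            wcc=float(row.wcc),
            dauno_dose=str(row.dauno_dose),
            regimen="" if pd.isna(row.regimen) else str(row.regimen),
        )
        hist = EventHistory(
            induction_given=_opt_bool(row.induction_given),
            cr1_time=_opt_float(row.cr1_time),
            cr1_via_salvage=_opt_bool(row.cr1_via_salvage),
            relapse_time=_opt_float(row.relapse_time),
            hsct_time=_opt_float(row.hsct_time),
            death_time=_opt_float(row.death_time),
            death_context="none" if pd.isna(row.death_context) else str(row.death_context),
            last_followup=float(row.last_followup),
        )
        patient = PatientRecord(pid, cov, tuple(by_patient.get(pid, ())), hist)
        validate_patient(patient)
        patients.append(patient)
    return Cohort(tuple(patients), provenance="imported")


def cohort_to_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort as (clinical, mutations) DataFrames in the exchange layout."""
    clin_rows, mut_rows = [], []
    for p in cohort:
        h, c = p.history, p.covariates
        clin_rows.append({
            "patient_id": p.patient_id, "age": c.age, "sex": c.sex, "wcc": c.wcc,
            "dauno_dose": c.dauno_dose, "regimen": c.regimen,
            "induction_given": h.induction_given, "cr1_time": h.cr1_time,
            "cr1_via_salvage": h.cr1_via_salvage, "relapse_time": h.relapse_time,
            "hsct_time": h.hsct_time, "death_time": h.death_time,
            "death_context": h.death_context, "last_followup": h.last_followup,
        })
        for m in p.mutations:
            mut_rows.append({"patient_id": m.patient_id, "gene": m.gene,
                             "subtype": m.subtype, "vaf": m.vaf})
    clin = pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS)
    muts = pd.DataFrame(mut_rows, columns=MUTATION_COLUMNS)
    return clin, muts


def write_cohort(cohort: Cohort, clinical_path, mutations_path) -> None:
    """Serialize a cohort; ``read_cohort`` on the output reproduces it
    field-for-field (floats written at shortest round-trip precision,
    missing values as empty cells)."""
    clinical_path, mutations_path = Path(clinical_path), Path(mutations_path)
    clin, muts = cohort_to_frames(cohort)
    try:
        clin.to_csv(clinical_path, sep=_sep_for(clinical_path), index=False)
        muts.to_csv(mutations_path, sep=_sep_for(mutations_path), index=False)
    except OSError as exc:
        raise OSError(f"writing cohort to {clinical_path} / {mutations_path}: {exc}") from exc


def maf_to_mutation_table(maf: pd.DataFrame, patient_column: str = "Tumor_Sample_Barcode") -> pd.DataFrame:
    """Convert a MAF-style frame (Hugo_Symbol, t_alt_count, t_depth) into
    the package's mutation-table layout.  Adapter only; not a core path."""
    required = ["Hugo_Symbol", "t_alt_count", "t_depth", patient_column]
    missing = [c for c in required if c not in maf.columns]
    if missing:
        raise SchemaError(f"MAF frame missing column(s): {', '.join(missing)}")
    out = pd.DataFrame({
        "patient_id": maf[patient_column].astype(str),
        "gene": maf["Hugo_Symbol"].astype(str).str.upper(),
        "subtype": maf.get("HGVSp_Short", pd.Series([""] * len(maf))).fillna(""),
        "vaf": maf["t_alt_count"].astype(float) / maf["t_depth"].astype(float),
    })
    return out
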