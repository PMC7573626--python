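"""Deterministic genotype classification for cytogenetically normal AML.

Three stratifications are computed per patient from the mutation list
alone (the cohort is cytogenetically normal, so no karyotype enters):

* the five genotype-combination categories —
  1: NPM1 mutation only; 2: all wild type; 3: NPM1 mutation + FLT3-ITD;
  4: FLT3-ITD only; 5: DNMT3A mutation irrespective of NPM1/FLT3 status.
  "Only" / "wild type" refer to the NPM1 / FLT3-ITD / DNMT3A triplet;
  other genes never change the category.
* the gene-only ELN 2017 risk group (favorable / intermediate / adverse),
  with the FLT3-ITD burden dichotomized at allelic ratio 0.5, i.e.
  VAF >= 0.33;
* the DNMT3A-modified ELN group: any DNMT3A mutation is an additional
  unfavorable factor pushing the patient to adverse.

The ELN rule table is data (`DEFAULT_ELN_RULES`) so alternative readings
— e.g. whether RUNX1/ASXL1 adverse status yields to a co-occurring
favorable-defining lesion — are testable without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .schema import Cohort, MutationCall

__all__ = [
    "GenotypeClassification",
    "ElnRules",
    "DEFAULT_ELN_RULES",
    "HIGH_ITD_VAF",
    "vaf_to_allelic_ratio",
    "classify_flt3_itd",
    "classify_category",
    "classify_eln2017",
    "classify_eln_dnmt3a",
    "classify_patient",
    "classify_cohort",
]

#: VAF cut defining high-burden FLT3-ITD; corresponds to allelic ratio 0.5.
HIGH_ITD_VAF = 0.33


@dataclass(frozen=True)
class ElnRules:
    """Configurable gene-only ELN 2017 rule table.

    ``adverse_genes`` are adverse when mutated (any subtype);
    ``cebpa_favorable_subtypes`` are the CEBPA subtype labels counted as
    biallelic/double-mutant; ``adverse_yields_to_favorable`` applies the
    guideline caveat that RUNX1/ASXL1 should not mark a patient adverse
    when a favorable-defining lesion co-occurs.
    """

    adverse_genes: frozenset[str] = frozenset({"RUNX1", "ASXL1", "TP53"})
    yielding_adverse_genes: frozenset[str] = frozenset({"RUNX1", "ASXL1"})
    cebpa_favorable_subtypes: frozenset[str] = frozenset({"biallelic", "DM", "dm"})
    adverse_yields_to_favorable: bool = True


DEFAULT_ELN_RULES = ElnRules()


@dataclass(frozen=True)
class GenotypeClassification:
    category: int
    flt3_itd_level: str  # absent | low | high
    eln2017: str         # favorable | intermediate | adverse
    eln_dnmt3a: str
    flags: frozenset[str] = frozenset()


def vaf_to_allelic_ratio(vaf: float) -> float:
    """Mutant/wild-type allelic ratio from a variant allele frequency.

    AR = VAF / (1 - VAF); strictly increasing on [0, 1).  The high-ITD
    cut VAF = 1/3 maps to AR = 0.5.
    """
    if not (0.0 <= vaf < 1.0):
        raise ValueError(f"allelic ratio undefined for vaf={vaf!r} (need 0 <= vaf < 1)")
    return vaf / (1.0 - vaf)


def _itd_calls(mutations: Iterable[MutationCall]) -> list[MutationCall]:
    return [m for m in mutations if m.gene == "FLT3" and m.subtype.upper().startswith("ITD")]


def classify_flt3_itd(mutations: Sequence[MutationCall]) -> str:
    """FLT3-ITD burden level: absent, low (max VAF < 0.33) or high.

    FLT3-TKD calls never count; with multiple ITD calls the maximum VAF
    decides (the question is whether a high-burden ITD clone is present).
    """
    itds = _itd_calls(mutations)
    if not itds:
        return "absent"
    return "high" if max(m.vaf for m in itds) >= HIGH_ITD_VAF else "low"


def classify_category(mutations: Sequence[MutationCall]) -> tuple[int, frozenset[str]]:
    """Five-category genotype label plus subgroup flags.

    DNMT3A trumps everything (Category 5); otherwise the NPM1-mutation x
    FLT3-ITD-presence table applies.  ITD *presence* is what matters here,
    regardless of burden level.  An IDH1 R132H call in Category 2 raises
    the ``idh1_r132h`` flag for the subgroup analysis.
    """
    has_dnmt3a = any(m.gene == "DNMT3A" for m in mutations)
    has_npm1 = any(m.gene == "NPM1" for m in mutations)
    has_itd = bool(_itd_calls(mutations))
    if has_dnmt3a:
        category = 5
    elif has_npm1 and has_itd:
        category = 3
    elif has_npm1:
        category = 1
    elif has_itd:
        category = 4
    else:
        category = 2
    flags = set()
    if category == 2 and any(
        m.gene == "IDH1" and m.subtype.upper() == "R132H" for m in mutations
    ):
        flags.add("idh1_r132h")
    return category, frozenset(flags)


def classify_eln2017(
    mutations: Sequence[MutationCall],
    flt3_itd_level: str,
    rules: ElnRules = DEFAULT_ELN_RULES,
) -> str:
    """Gene-only ELN 2017 risk group for a cytogenetically normal patient.

    favorable: NPM1-mutated with ITD absent/low, or biallelic CEBPA;
    adverse: NPM1-wild-type with ITD-high, or a mutated adverse gene
    (RUNX1/ASXL1 yield to a co-occurring favorable lesion when the
    configured caveat is on); intermediate: everything else.
    """
    has_npm1 = any(m.gene == "NPM1" for m in mutations)
    has_cebpa_dm = any(
        m.gene == "CEBPA" and m.subtype in rules.cebpa_favorable_subtypes
        for m in mutations
    )
    favorable_lesion = (has_npm1 and flt3_itd_level in ("absent", "low")) or has_cebpa_dm

    adverse_hits = {m.gene for m in mutations if m.gene in rules.adverse_genes}
    if rules.adverse_yields_to_favorable and favorable_lesion:
        adverse_hits -= rules.yielding_adverse_genes
    if (not has_npm1 and flt3_itd_level == "high") or adverse_hits:
        return "adverse"
    if favorable_lesion:
        return "favorable"
    return "intermediate"


def classify_eln_dnmt3a(mutations: Sequence[MutationCall], eln2017: str) -> str:
    """DNMT3A-modified ELN group: any DNMT3A mutation (subtype-agnostic)
    reclassifies the patient as adverse; otherwise unchanged."""
    if any(m.gene == "DNMT3A" for m in mutations):
        return "adverse"
    return eln2017


def classify_patient(
    mutations: Sequence[MutationCall], rules: ElnRules = DEFAULT_ELN_RULES
) -> GenotypeClassification:
    level = classify_flt3_itd(mutations)
    category, flags = classify_category(mutations)
    eln = classify_eln2017(mutations, level, rules)
    return GenotypeClassification(
        category=category,
        flt3_itd_level=level,
        eln2017=eln,
        eln_dnmt3a=classify_eln_dnmt3a(mutations, eln),
        flags=flags,
    )


def classify_cohort(cohort: Cohort, rules: ElnRules = DEFAULT_ELN_RULES) -> pd.DataFrame:
    """Per-patient classification table (one row per patient)."""
    rows = []
    for p in cohort:
        cls = classify_patient(p.mutations, rules)
        rows.append({
            "patient_id": p.patient_id,
            "category": cls.category,
            "flt3_itd_level": cls.flt3_itd_level,
            "eln2017": cls.eln2017,
            "eln_dnmt3a": cls.eln_dnmt3a,
            "flags": ";".join(sorted(cls.flags)),
        })
    return pd.DataFrame(rows, columns=[
        "patient_id", "category", "flt3_itd_level", "eln2017", "eln_dnmt3a", "flags",
    ])
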