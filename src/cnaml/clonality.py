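"""VAF-based clonal architecture calls and cohort-wide subtype enumeration.

Each mutation's clone fraction is 2*VAF clipped to [0, 1] (heterozygous
autosomal assumption; copy-number effects are out of scope).  Within a
patient, calls whose clone fraction reaches ``rel_threshold`` times the
largest clone fraction form the dominant tier: a singleton tier is a
dominant clone, a multi-member tier is co-dominant, and everything below
is subclonal.  The rule is purely relative, so rescaling all of a
patient's VAFs by a common factor never changes any status.

A patient's clonal subtype key is the canonical string
``"<dominant set> | <subclone set>"`` with ``GENE:subtype`` tokens sorted
within each set — permutation-invariant, but sensitive to which role a
gene plays (dominant NPM1 with subclonal FLT3-ITD is a different subtype
from the converse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .schema import Cohort, MutationCall

__all__ = [
    "ClonalCall",
    "call_clonality",
    "subtype_key",
    "enumerate_subtypes",
    "bubble_diagram",
]

DEFAULT_REL_THRESHOLD = 0.67


@dataclass(frozen=True)
class ClonalCall:
    mutation: MutationCall
    clone_fraction: float
    status: str  # dominant | co_dominant | subclone


def _token(m: MutationCall) -> str:
    return f"{m.gene}:{m.subtype}" if m.subtype else m.gene


def call_clonality(
    mutations: Sequence[MutationCall],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    tol: float = 0.10,
) -> list[ClonalCall]:
    """Call each mutation dominant / co-dominant / subclonal.

    ``tol`` is reserved for future absolute-gap comparisons and does not
    affect the default relative rule.
    """
    if not mutations:
        raise ValueError("clonal architecture undefined for an all-wild-type patient")
    if not (0 < rel_threshold <= 1):
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold!r}")
    fractions = [min(2.0 * m.vaf, 1.0) for m in mutations]
    f_max = max(fractions)
    in_tier = [f_max == 0.0 or f >= rel_threshold * f_max for f in fractions]
    tier_status = "dominant" if sum(in_tier) == 1 else "co_dominant"
    return [
        ClonalCall(m, f, tier_status if top else "subclone")
        for m, f, top in zip(mutations, fractions, in_tier)
    ]


def subtype_key(calls: Sequence[ClonalCall]) -> str:
    """Canonical clonal-subtype key for one patient's calls."""
    dominant = sorted(_token(c.mutation) for c in calls if c.status != "subclone")
    sub = sorted(_token(c.mutation) for c in calls if c.status == "subclone")
    left = "+".join(dominant)
    right = "+".join(sub) if sub else "∅"
    return f"{left} | {right}"


def enumerate_subtypes(
    cohort: Cohort, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> pd.DataFrame:
    """Distinct clonal subtypes with counts and prevalences.

    Prevalence denominators count only patients with at least one
    detectable mutation.  Sorted by count descending, key ascending.
    """
    keys = [
        subtype_key(call_clonality(p.mutations, rel_threshold))
        for p in cohort
        if p.mutations
    ]
    if not keys:
        raise ValueError("no patient in the cohort carries a detectable mutation")
    counts = pd.Series(keys).value_counts()
    table = (
        counts.rename_axis("subtype")
        .reset_index(name="count")
        .sort_values(["count", "subtype"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    table["prevalence"] = table["count"] / len(keys)
    return table


def bubble_diagram(
    cohort: Cohort, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> list[dict]:
    """Bubble-diagram export: one outer bubble per dominant/co-dominant
    set (size = prevalence among mutated patients), inner bubbles for the
    subclone sets observed beneath it with their mean clone size relative
    to the dominant tier."""
    mutated = [p for p in cohort if p.mutations]
    if not mutated:
        raise ValueError("no patient in the cohort carries a detectable mutation")
    outer: dict[str, dict] = {}
    for p in mutated:
        calls = call_clonality(p.mutations, rel_threshold)
        dom = "+".join(sorted(_token(c.mutation) for c in calls if c.status != "subclone"))
        dom_size = max(c.clone_fraction for c in calls)
        entry = outer.setdefault(dom, {"dominant": dom, "n": 0, "inner": {}})
        entry["n"] += 1
        subs = [c for c in calls if c.status == "subclone"]
        if subs:
            key = "+".join(sorted(_token(c.mutation) for c in subs))
            rel = max(c.clone_fraction for c in subs) / dom_size if dom_size > 0 else 0.0
            inner = entry["inner"].setdefault(key, {"subclone": key, "n": 0, "rel_sizes": []})
            inner["n"] += 1
            inner["rel_sizes"].append(rel)
    result = []
    for entry in sorted(outer.values(), key=lambda e: (-e["n"], e["dominant"])):
        inner = [
            {
                "subclone": i["subclone"],
                "n": i["n"],
                "relative_size": sum(i["rel_sizes"]) / len(i["rel_sizes"]),
            }
            for i in sorted(entry["inner"].values(), key=lambda i: (-i["n"], i["subclone"]))
        ]
        result.append({
            "dominant": entry["dominant"],
            "n": entry["n"],
            "prevalence": entry["n"] / len(mutated),
            "subclones": inner,
        })
    return result


def clonality_table(cohort: Cohort, rel_threshold: float = DEFAULT_REL_THRESHOLD) -> pd.DataFrame:
    """Per-mutation clonality calls for every mutated patient."""
    rows = []
    for p in cohort:
        if not p.mutations:
            continue
        for c in call_clonality(p.mutations, rel_threshold):
            rows.append({
                "patient_id": p.patient_id,
                "gene": c.mutation.gene,
                "subtype": c.mutation.subtype,
                "vaf": c.mutation.vaf,
                "clone_fraction": c.clone_fraction,
                "status": c.status,
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "gene", "subtype", "vaf", "clone_fraction", "status",
    ])
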