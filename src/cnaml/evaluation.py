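"""Concordance-index evaluation and model comparison.

Harrell's C over right-censored survival data: among comparable patient
pairs (the smaller follow-up time is an event), the fraction where the
predicted risk orders the pair correctly, with half credit for tied
scores.  Uncertainty comes from a seeded patient-level bootstrap, and a
multistate model is compared with the ordinal ELN baseline
(favorable = 0, intermediate = 1, adverse = 2 — ties expected and
half-credited) by a paired bootstrap on the concordance difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype import classify_patient
from .multistate import MultistateModel, MultistateResults
from .schema import Cohort
from .survival import SurvivalRecord, cohort_endpoints

__all__ = [
    "ConcordanceResult",
    "ModelComparison",
    "concordance_index",
    "compare_models",
    "eln_baseline_scores",
    "train_validate",
]

ELN_ORDINAL = {"favorable": 0.0, "intermediate": 1.0, "adverse": 2.0}


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    n_comparable_pairs: int
    bootstrap_se: Optional[float]
    n_boot: int
    seed: Optional[int]


@dataclass(frozen=True)
class ModelComparison:
    c_model: float
    c_baseline: float
    delta: float
    relative_gain: float
    p_value: Optional[float]
    n_boot: int
    seed: Optional[int]


def _c_statistic(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, int]:
    """Vectorized Harrell's C; returns (c, number of comparable pairs)."""
    n = len(scores)
    t_i = times[:, None]
    t_j = times[None, :]
    e_i = events[:, None]
    # pair (i, j), i the earlier subject: comparable iff t_i < t_j and i had
    # an event, or t_i == t_j with exactly one event (the event-bearer fails first)
    comparable = (t_i < t_j) & e_i
    tied_time = (t_i == t_j) & e_i & ~events[None, :]
    comparable |= tied_time
    s_i = scores[:, None]
    s_j = scores[None, :]
    concordant = comparable & (s_i > s_j)
    tied_score = comparable & (s_i == s_j)
    num = concordant.sum() + 0.5 * tied_score.sum()
    den = comparable.sum()
    return (float(num / den) if den else float("nan")), int(den)


def _as_arrays(scores, records: Sequence[SurvivalRecord]):
    if isinstance(scores, pd.Series):
        ids = [r.patient_id for r in records]
        missing = [i for i in ids if i not in scores.index]
        if missing:
            raise ValueError(f"scores missing for patient(s): {missing[:5]}")
        s = scores.loc[ids].to_numpy(float)
    else:
        s = np.asarray(scores, float)
        if len(s) != len(records):
            raise ValueError("scores and records must align one-to-one")
    t = np.array([r.time for r in records], float)
    e = np.array([r.event for r in records], bool)
    return s, t, e


def concordance_index(
    scores,
    records: Sequence[SurvivalRecord],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> ConcordanceResult:
    """Harrell's concordance index with a seeded bootstrap SE.

    ``scores`` may be a pd.Series indexed by patient_id or an array
    aligned with ``records``; higher score = higher predicted risk.
    ``n_boot = 0`` skips the bootstrap (SE reported as None).
    """
    s, t, e = _as_arrays(scores, records)
    c, n_pairs = _c_statistic(s, t, e)
    if n_pairs == 0:
        raise ValueError("no comparable pairs (no events, or all times tied)")
    se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(s)
        cs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            cb, nb = _c_statistic(s[idx], t[idx], e[idx])
            if nb:
                cs.append(cb)
        se = float(np.std(cs, ddof=1)) if len(cs) > 1 else None
    return ConcordanceResult(c, n_pairs, se, n_boot, seed)


def compare_models(
    model_scores,
    baseline_scores,
    records: Sequence[SurvivalRecord],
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> ModelComparison:
    """Paired bootstrap comparison of two risk scores on the same patients.

    The two-sided p-value is the (+1-smoothed) fraction of bootstrap
    concordance differences crossing zero.
    """
    s_m, t, e = _as_arrays(model_scores, records)
    s_b, t2, e2 = _as_arrays(baseline_scores, records)
    if not (np.array_equal(t, t2) and np.array_equal(e, e2)):
        raise ValueError("model and baseline scores must cover the same patients")
    c_m, n_pairs = _c_statistic(s_m, t, e)
    c_b, _ = _c_statistic(s_b, t, e)
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    delta = c_m - c_b
    p = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(t)
        deltas = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            cm, nb = _c_statistic(s_m[idx], t[idx], e[idx])
            if not nb:
                continue
            cb, _ = _c_statistic(s_b[idx], t[idx], e[idx])
            deltas.append(cm - cb)
        deltas = np.asarray(deltas)
        if len(deltas):
            # two-sided: bootstrap deltas on the far side of 0 from the estimate
            crossing = np.sum(deltas <= 0) if delta > 0 else np.sum(deltas >= 0)
            p = float(min(1.0, 2.0 * (crossing + 1) / (len(deltas) + 1)))
    return ModelComparison(
        c_model=c_m, c_baseline=c_b, delta=delta,
        relative_gain=delta / c_b if c_b else float("nan"),
        p_value=p, n_boot=n_boot, seed=seed,
    )


def eln_baseline_scores(cohort: Cohort, modified: bool = False) -> pd.Series:
    """Ordinal risk score from the (optionally DNMT3A-modified) ELN group."""
    scores = {}
    for p in cohort:
        cls = classify_patient(p.mutations)
        group = cls.eln_dnmt3a if modified else cls.eln2017
        scores[p.patient_id] = ELN_ORDINAL[group]
    return pd.Series(scores, name="eln")


def _refractory_hsct_filter(cohort: Cohort) -> Cohort:
    """Drop patients transplanted without ever reaching CR1 (refractory-
    stage HSCT), mirroring the validation-cohort exclusion."""
    return cohort.subset(
        lambda p: not (p.history.hsct_time is not None and p.history.cr1_time is None)
    )


def evaluate_cohort(
    results: MultistateResults,
    cohort: Cohort,
    endpoint: str = "LFS",
    horizon: float = 60.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> ModelComparison:
    """Concordance comparison of a fitted multistate model against the
    ordinal ELN baseline on one cohort (default endpoint: LFS from CR1)."""
    in_cr = cohort.subset(lambda p: p.history.cr1_time is not None)
    if len(in_cr) == 0:
        raise ValueError("no CR1 patients to evaluate")
    records = cohort_endpoints(in_cr, endpoint)
    model_scores = results.risk_scores(in_cr, horizon=horizon)
    baseline = eln_baseline_scores(in_cr)
    return compare_models(model_scores, baseline, records, n_boot=n_boot, seed=seed)


def train_validate(
    train: Cohort,
    validate: Cohort,
    family: str = "exponential",
    covariate_spec: Optional[dict] = None,
    endpoint: str = "LFS",
    horizon: float = 60.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> dict:
    """Fit on ``train`` only; evaluate model-vs-ELN concordance on both
    cohorts.  The validation cohort is filtered for refractory-stage HSCT
    before evaluation.  Returns {"train": ModelComparison,
    "validate": ModelComparison, "results": MultistateResults}."""
    results = MultistateModel(train, family=family, covariate_spec=covariate_spec).fit()
    filtered = _refractory_hsct_filter(validate)
    if len(filtered.subset(lambda p: p.history.cr1_time is not None)) == 0:
        raise ValueError("validation cohort empty after refractory-HSCT filtering")
    return {
        "results": results,
        "train": evaluate_cohort(results, train, endpoint, horizon, n_boot, seed),
        "validate": evaluate_cohort(results, filtered, endpoint, horizon, n_boot, seed),
    }
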