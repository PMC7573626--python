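"""Synthetic CN-AML cohort generator.

The real study cohort is not public, so every downstream stage is
exercised on simulated patients whose statistical structure mirrors what
the analysis assumes:

* **Genotypes** are drawn gene-by-gene from marginal mutation
  frequencies tilted by pairwise co-occurrence log-odds (a pairwise
  Gibbs model, 50 burn-in sweeps per cohort, vectorized across
  patients).  With all pairwise adjustments at zero the marginals are
  exact Bernoulli frequencies.
* **VAFs**: the first mutation drawn for a patient is always the
  founding/dominant clone, with VAF from a truncated normal centered in
  the 0.40-0.50 band; later mutations are subclonal with a per-gene
  probability (elevated for FLT3-ITD, which is predominantly subclonal)
  and then take a uniform low VAF, otherwise they join the dominant
  clone's VAF band.
* **Event histories** follow the outcome tree of induction AML therapy:
  a logistic model for CR/CRi after first induction, salvage CR for a
  fraction of failures, then competing exponential clocks from CR1
  (relapse vs treatment-related mortality) and from relapse (death in
  relapse), each with hazard lambda0 * exp(sum beta x).  HSCT at CR1 is
  assigned by a risk-group policy and acts as a time-fixed covariate
  from CR1; the transplant itself is recorded at a fixed delay provided
  the patient is still in remission then.  Administrative censoring at
  ``followup_max`` months.

The same seed always yields a bitwise-identical cohort.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import yaml

from .features import SUPPORTED_COVARIATES, covariate_value
from .genotype import classify_patient
from .schema import (
    ClinicalCovariates,
    Cohort,
    EventHistory,
    MutationCall,
    PatientRecord,
)

__all__ = ["GeneratorConfig", "generate_cohort", "true_risk_score", "default_config"]

TRANSITIONS = ("cr1_relapse", "cr1_trm", "relapse_death", "refractory_death")

# lesion key -> (gene symbol, [(subtype, weight), ...])
LESION_CALLS: dict[str, tuple[str, list[tuple[str, float]]]] = {
    "NPM1": ("NPM1", [("typeA", 0.75), ("typeB", 0.10), ("typeD", 0.05), ("other", 0.10)]),
    "DNMT3A": ("DNMT3A", [("R882", 0.60), ("non-R882", 0.40)]),
    "FLT3-ITD": ("FLT3", [("ITD", 1.0)]),
    "FLT3-TKD": ("FLT3", [("TKD-D835", 0.80), ("TKD-nonD835", 0.20)]),
    "IDH1": ("IDH1", [("R132H", 0.60), ("R132C", 0.20), ("R132S", 0.10), ("R132L", 0.10)]),
    "IDH2": ("IDH2", [("R140Q", 0.80), ("R172K", 0.20)]),
    "CEBPA": ("CEBPA", [("biallelic", 1.0)]),
}

DEFAULT_GENE_FREQS = {
    "NPM1": 0.40,
    "DNMT3A": 0.22,
    "FLT3-ITD": 0.22,
    "FLT3-TKD": 0.10,
    "NRAS": 0.12,
    "IDH2": 0.12,
    "IDH1": 0.08,
    "CEBPA": 0.08,
    "TET2": 0.10,
    "WT1": 0.08,
    "RUNX1": 0.06,
    "ASXL1": 0.04,
    "KRAS": 0.04,
    "TP53": 0.02,
}

DEFAULT_COOCCURRENCE = {
    ("NPM1", "DNMT3A"): 0.9,
    ("NPM1", "FLT3-ITD"): 0.7,
    ("DNMT3A", "FLT3-ITD"): 0.5,
    ("NPM1", "CEBPA"): -2.0,
    ("NPM1", "RUNX1"): -2.0,
    ("NPM1", "TP53"): -1.5,
    ("IDH1", "IDH2"): -2.5,
}

DEFAULT_TRANSITION_HAZARDS = {
    "cr1_relapse": 0.008,
    "cr1_trm": 0.003,
    "relapse_death": 0.05,
    "refractory_death": 0.08,
}

DEFAULT_COVARIATE_EFFECTS = {
    "cr1_relapse": {
        "hsct": -0.7, "age_c": 0.01, "log10_wcc": 0.4,
        "cat2": 0.3, "cat3": 0.5, "cat4": 0.6, "cat5": 0.8,
    },
    "cr1_trm": {"hsct": 0.9, "age_c": 0.03},
    "relapse_death": {"cat5": 0.4, "log10_wcc": 0.3},
    "refractory_death": {},
}

DEFAULT_HSCT_POLICY = {"favorable": 0.15, "intermediate": 0.45, "adverse": 0.65}

DEFAULT_CR_PROBABILITY = {
    "intercept": 1.0, "log10_wcc": -0.35, "age_c": -0.01,
    "cat2": -0.1, "cat3": -0.2, "cat4": -0.5, "cat5": -0.4,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort; the seed determines the
    output bit-for-bit."""

    n_patients: int = 459
    seed: int = 0
    gene_freqs: dict = field(default_factory=lambda: dict(DEFAULT_GENE_FREQS))
    cooccurrence_log_odds: dict = field(default_factory=lambda: dict(DEFAULT_COOCCURRENCE))
    vaf_dominant: tuple = (0.44, 0.05)
    vaf_subclone: tuple = (0.08, 0.28)
    p_subclone: float = 0.35
    p_subclone_overrides: dict = field(default_factory=lambda: {"FLT3-ITD": 0.70})
    transition_hazards: dict = field(default_factory=lambda: dict(DEFAULT_TRANSITION_HAZARDS))
    covariate_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()
    })
    hsct_policy: dict = field(default_factory=lambda: dict(DEFAULT_HSCT_POLICY))
    cr_probability: dict = field(default_factory=lambda: dict(DEFAULT_CR_PROBABILITY))
    p_salvage_cr: float = 0.74
    p_induction: float = 0.95
    hsct_delay: float = 4.0
    followup_max: float = 120.0

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        probs = list(self.gene_freqs.values()) + list(self.hsct_policy.values()) + [
            self.p_subclone, self.p_salvage_cr, self.p_induction,
        ] + list(self.p_subclone_overrides.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for k in TRANSITIONS:
            if k not in self.transition_hazards:
                raise ValueError(f"transition_hazards missing {k!r}")
            if not self.transition_hazards[k] >= 0:
                raise ValueError(f"hazard for {k!r} must be >= 0")
        for trans, effects in self.covariate_effects.items():
            if trans not in TRANSITIONS:
                raise ValueError(f"unknown transition {trans!r} in covariate_effects")
            bad = [c for c in effects if c not in SUPPORTED_COVARIATES]
            if bad:
                raise ValueError(
                    f"unknown covariate name(s) {bad} for transition {trans!r}; "
                    f"supported: {list(SUPPORTED_COVARIATES)}"
                )
        bad = [c for c in self.cr_probability if c != "intercept" and c not in SUPPORTED_COVARIATES]
        if bad:
            raise ValueError(f"unknown covariate name(s) {bad} in cr_probability")
        if self.followup_max <= 0 or self.hsct_delay < 0:
            raise ValueError("followup_max must be positive and hsct_delay non-negative")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cooccurrence_log_odds"] = {
            "|".join(k): v for k, v in self.cooccurrence_log_odds.items()
        }
        d["vaf_dominant"] = list(self.vaf_dominant)
        d["vaf_subclone"] = list(self.vaf_subclone)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "cooccurrence_log_odds" in d:
            d["cooccurrence_log_odds"] = {
                tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                for k, v in d["cooccurrence_log_odds"].items()
            }
        for key in ("vaf_dominant", "vaf_subclone"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _sample_genotypes(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """n x G binary genotype matrix from the pairwise Gibbs model."""
    genes = list(config.gene_freqs)
    g = len(genes)
    p = np.clip(np.array([config.gene_freqs[k] for k in genes]), 0.0, 1.0)
    n = config.n_patients

    hard0, hard1 = p <= 0.0, p >= 1.0
    with np.errstate(divide="ignore"):
        alpha = np.where(hard0 | hard1, 0.0, np.log(p / (1.0 - p)))
    W = np.zeros((g, g))
    index = {k: i for i, k in enumerate(genes)}
    for (a, b), lo in config.cooccurrence_log_odds.items():
        if a in index and b in index:
            W[index[a], index[b]] += lo
            W[index[b], index[a]] += lo

    X = (rng.random((n, g)) < p).astype(float)
    if np.any(W != 0.0):
        for _ in range(50):  # burn-in sweeps
            for j in range(g):
                prob = _sigmoid(alpha[j] + X @ W[:, j])
                X[:, j] = (rng.random(n) < prob).astype(float)
    X[:, hard0] = 0.0
    X[:, hard1] = 1.0
    return X.astype(bool)


def _draw_vaf_dominant(config, rng) -> float:
    mean, sd = config.vaf_dominant
    if sd <= 0:
        return float(np.clip(mean, 0.0, 1.0))
    # truncated-normal by redraw, clipped as a last resort
    for _ in range(100):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 1.0:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _mutations_for_patient(pid, lesions, config, rng) -> tuple[MutationCall, ...]:
    order = list(lesions)
    rng.shuffle(order)
    calls = []
    for i, lesion in enumerate(order):
        gene, subtypes = LESION_CALLS.get(lesion, (lesion, [("", 1.0)]))
        labels = [s for s, _ in subtypes]
        weights = np.array([w for _, w in subtypes])
        subtype = labels[rng.choice(len(labels), p=weights / weights.sum())]
        p_sub = config.p_subclone_overrides.get(lesion, config.p_subclone)
        if i > 0 and rng.random() < p_sub:
            lo, hi = config.vaf_subclone
            vaf = float(rng.uniform(lo, hi))
        else:
            vaf = _draw_vaf_dominant(config, rng)
        calls.append(MutationCall(pid, gene.upper(), subtype, vaf))
    return tuple(calls)


def _linear_predictor(effects: dict, values: dict) -> float:
    return sum(beta * values[name] for name, beta in effects.items())


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate a full cohort under ``config`` (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    genes = list(config.gene_freqs)

    X = _sample_genotypes(config, rng)

    age = 18.0 + 42.0 * rng.beta(3.5, 1.5, size=n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    wcc = np.clip(10.0 ** rng.normal(1.1, 0.5, size=n), 0.3, 400.0)
    induction = rng.random(n) < config.p_induction
    dose_pick = rng.random(n)
    regimen_pick = rng.random(n)

    patients = []
    for i in range(n):
        pid = f"P{i+1:05d}"
        lesions = [genes[j] for j in range(len(genes)) if X[i, j]]
        mutations = _mutations_for_patient(pid, lesions, config, rng)
        cls = classify_patient(mutations)

        if induction[i]:
            dauno = "60" if dose_pick[i] < 0.60 else ("90" if dose_pick[i] < 0.95 else "other")
            regimen = "7+3" if regimen_pick[i] < 0.96 else "5+2"
        else:
            dauno, regimen = "none", "palliative"
        cov = ClinicalCovariates(
            age=float(age[i]), sex=str(sex[i]), wcc=float(wcc[i]),
            dauno_dose=dauno, regimen=regimen,
        )

        values = {
            "age_c": cov.age - 49.0,
            "sex_female": 1.0 if cov.sex == "female" else 0.0,
            "log10_wcc": math.log10(max(cov.wcc, 0.1)),
            "cat2": 1.0 if cls.category == 2 else 0.0,
            "cat3": 1.0 if cls.category == 3 else 0.0,
            "cat4": 1.0 if cls.category == 4 else 0.0,
            "cat5": 1.0 if cls.category == 5 else 0.0,
            "hsct": 0.0,
        }

        # --- induction outcome -------------------------------------
        cr1_time = None
        via_salvage = False
        if induction[i]:
            eta = config.cr_probability.get("intercept", 0.0) + _linear_predictor(
                {k: v for k, v in config.cr_probability.items() if k != "intercept"},
                values,
            )
            if rng.random() < _sigmoid(eta):
                cr1_time = float(rng.uniform(0.9, 1.8))
            elif rng.random() < config.p_salvage_cr:
                cr1_time = float(rng.uniform(2.5, 4.5))
                via_salvage = True

        relapse_time = hsct_time = death_time = None
        death_context = "none"
        last_fu = config.followup_max

        if cr1_time is None:
            # refractory / palliative course
            lam = config.transition_hazards["refractory_death"] * math.exp(
                _linear_predictor(config.covariate_effects.get("refractory_death", {}), values)
            )
            t_assess = 1.0 if not induction[i] else 2.0
            t_death = t_assess + (rng.exponential(1.0 / lam) if lam > 0 else math.inf)
            if t_death <= config.followup_max:
                death_time = float(t_death)
                death_context = "death_refractory"
                last_fu = death_time
        else:
            # HSCT assignment acts as a time-fixed covariate from CR1
            assigned = rng.random() < config.hsct_policy.get(cls.eln_dnmt3a, 0.0)
            values["hsct"] = 1.0 if assigned else 0.0

            lam_rel = config.transition_hazards["cr1_relapse"] * math.exp(
                _linear_predictor(config.covariate_effects.get("cr1_relapse", {}), values)
            )
            lam_trm = config.transition_hazards["cr1_trm"] * math.exp(
                _linear_predictor(config.covariate_effects.get("cr1_trm", {}), values)
            )
            t_rel = rng.exponential(1.0 / lam_rel) if lam_rel > 0 else math.inf
            t_trm = rng.exponential(1.0 / lam_trm) if lam_trm > 0 else math.inf
            censor = config.followup_max - cr1_time
            t_event = min(t_rel, t_trm)

            if assigned and t_event > config.hsct_delay and \
                    cr1_time + config.hsct_delay <= config.followup_max:
                hsct_time = float(cr1_time + config.hsct_delay)

            if t_event >= censor or t_event == math.inf:
                pass  # alive in CR1 at administrative censoring
            elif t_trm <= t_rel:
                death_time = float(cr1_time + t_trm)
                death_context = "TRM_in_remission"
                last_fu = death_time
            else:
                relapse_time = float(cr1_time + t_rel)
                eff = dict(config.covariate_effects.get("relapse_death", {}))
                lam_dr = config.transition_hazards["relapse_death"] * math.exp(
                    _linear_predictor(eff, values)
                )
                t_dr = rng.exponential(1.0 / lam_dr) if lam_dr > 0 else math.inf
                if relapse_time + t_dr <= config.followup_max:
                    death_time = float(relapse_time + t_dr)
                    death_context = "death_in_relapse"
                    last_fu = death_time

        hist = EventHistory(
            induction_given=bool(induction[i]),
            cr1_time=cr1_time,
            cr1_via_salvage=via_salvage,
            relapse_time=relapse_time,
            hsct_time=hsct_time,
            death_time=death_time,
            death_context=death_context,
            last_followup=float(last_fu),
        )
        patients.append(PatientRecord(pid, cov, mutations, hist))

    return Cohort(tuple(patients), provenance="synthetic", config_hash=config.config_hash())


def true_risk_score(config: GeneratorConfig, patient: PatientRecord) -> float:
    """Ground-truth linear predictor (sum beta*x) of the CR1->relapse
    transition for a patient generated under ``config``; the oracle for
    parameter-recovery and concordance tests."""
    effects = config.covariate_effects.get("cr1_relapse", {})
    return float(sum(beta * covariate_value(patient, name) for name, beta in effects.items()))
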