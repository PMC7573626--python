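# cnaml

Genotype-driven prognostication toolkit for **de novo cytogenetically
normal acute myeloid leukemia (CN-AML) in young adults** (18–60 years).

About half of AML presents with a normal karyotype, where prognosis must
be read from recurrent gene mutations rather than cytogenetics.  The key
clinical decision comes at first complete remission (CR1): consolidate
with chemotherapy alone, or proceed to allogeneic stem-cell
transplantation (allo-HSCT), which lowers relapse risk at the price of
treatment-related mortality (TRM).  `cnaml` implements the analysis
chain that supports that decision:

* **Genotype rules** — the five mutation-combination categories
  (1: *NPM1* only; 2: all wild type; 3: *NPM1* + *FLT3*-ITD;
  4: *FLT3*-ITD only; 5: any *DNMT3A* mutation), gene-only **ELN 2017**
  risk (with the *FLT3*-ITD burden dichotomized at allelic ratio
  AR = VAF/(1−VAF) ≥ 0.5, i.e. VAF ≥ 0.33), and the **DNMT3A-modified
  ELN** stratification that treats any *DNMT3A* mutation as an
  additional adverse factor.
* **Clonal architecture** — dominant / co-dominant / subclonal calls
  from variant allele frequencies (clone fraction = 2·VAF under the
  heterozygous autosomal assumption), canonical clonal-subtype keys and
  cohort-wide subtype enumeration (bubble-diagram export).
* **Survival engine** — LFS / EFS / OS endpoint construction (optional
  censoring at HSCT), self-contained Kaplan–Meier with Greenwood
  variance, k-group log-rank, and Cox proportional hazards (Breslow
  ties, Newton–Raphson), every estimator verifiable against hand
  computation.
* **Multistate outcome model** — cause-specific parametric hazards on
  the post-remission state graph
  `CR1 → RELAPSE → DEATH_RELAPSE`, `CR1 → TRM`, with covariates (age,
  sex, log₁₀ WCC, genotype category, HSCT-at-CR1).  Per-transition
  hazard: h_k(t) = λ₀ₖ γₖ t^{γₖ−1} exp(βₖᵀx).  Solving the Kolmogorov
  forward equations yields per-patient state-occupancy ("sediment
  plot") curves and leukemia-free survival under HSCT-at-CR1 vs
  no-HSCT strategies.
* **Evaluation** — Harrell's concordance index with seeded bootstrap,
  paired-bootstrap comparison against the ordinal ELN baseline
  (favorable = 0, intermediate = 1, adverse = 2), and a train/validate
  workflow.
* **Synthetic cohorts** — patient-level AML data are rarely shareable,
  so a generator with known ground truth (pairwise-Gibbs genotypes,
  clonal VAF structure, competing-risk event histories) makes every
  stage testable end to end.

## Worked example

```python
import pandas as pd
from cnaml import GeneratorConfig, generate_cohort, MultistateModel
from cnaml.evaluation import evaluate_cohort

cohort = generate_cohort(GeneratorConfig(n_patients=459, seed=1))
results = MultistateModel(cohort, family="exponential").fit()

# a 25-year-old woman, WCC 10x10^9/L, genotype category 1 (NPM1 only)
x = pd.Series({"age_c": 25 - 49, "sex_female": 1.0, "log10_wcc": 1.0,
               "cat2": 0, "cat3": 0, "cat4": 0, "cat5": 0, "hsct": 0})
print(results.compare_strategies(x).to_string(index=False))
```

```
 horizon_months strategy    P_CR1  P_DEATH_RELAPSE
           24.0 hsct_cr1 0.849307              NaN
           60.0 hsct_cr1 0.664754         0.206809
           24.0  no_hsct 0.778521              NaN
           60.0  no_hsct 0.534782         0.356933
```

`P_CR1` is the predicted leukemia-free survival: with transplantation at
CR1 this patient's 2- and 5-year LFS are 85% and 66%; declining HSCT
drops them to 78% and 53%, with a 36% chance of death in relapse by five
years.  The same call for a category-5 (*DNMT3A*-mutated) patient with
WCC 100 gives 59%/27% with HSCT versus 40%/10% without (84% death in
relapse) — the high-risk genotype gains far more from transplantation.

Comparing the model's ranking with the ELN ordinal baseline on the same
synthetic cohort:

```python
cmp_ = evaluate_cohort(results, cohort, n_boot=200, seed=1)
print(f"C model {cmp_.c_model:.3f}  C ELN {cmp_.c_baseline:.3f}  "
      f"delta {cmp_.delta:.3f}  p {cmp_.p_value:.4f}")
# C model 0.592  C ELN 0.508  delta 0.084  p 0.0100
```

The generator's true hazards depend on *DNMT3A* (category 5), which the
plain ELN grouping cannot see, so the fitted multistate model
out-discriminates the baseline.

## Command line

The same pipeline is scriptable via the `cnaml` console command:

```bash
cnaml simulate --seed 7 --n 459 --out-prefix cohort
cnaml classify --clinical cohort.clinical.tsv --mutations cohort.mutations.tsv --out risk.tsv
cnaml clones   --clinical cohort.clinical.tsv --mutations cohort.mutations.tsv --out-prefix clones
cnaml survival --clinical cohort.clinical.tsv --mutations cohort.mutations.tsv \
               --endpoint lfs --group-by eln_dnmt3a --out-prefix surv
cnaml fit      --clinical cohort.clinical.tsv --mutations cohort.mutations.tsv --out model.json
cnaml predict  --model model.json --age 25 --sex female --wcc 10 --category 1 --out-prefix pred
cnaml evaluate --train-clinical cohort.clinical.tsv --train-mutations cohort.mutations.tsv \
               --n-boot 500 --seed 1 --out eval.json
cnaml run      --seed 7 --out-dir full_run     # all stages + hashed manifest
```

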