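# Methods

`cnaml` models the post-diagnosis course of de novo cytogenetically
normal AML (CN-AML) in adults aged 18–60 and the value of allogeneic
HSCT at first complete remission (CR1).  This note records the models,
the defaults and why, what the synthetic cohorts do and do not emulate,
and the numerical choices.

## Genotype classification

Classification is purely rule-based and total: every mutation list maps
to exactly one value of each label.

* **Five categories.**  Any *DNMT3A* mutation (either R882 or non-R882)
  dominates (category 5); otherwise the NPM1-mutation × FLT3-ITD-presence
  table applies (1: *NPM1* only, 2: all wild type, 3: both, 4: ITD only).
  "Wild type" refers to the *NPM1*/*FLT3*-ITD/*DNMT3A* triplet — other
  genes never move the category, which is what makes the within-category-2
  IDH1-R132H subgroup flag meaningful.  ITD *presence* (any burden)
  defines categories 3/4; burden matters only to ELN.
* **FLT3-ITD burden.**  AR = VAF/(1−VAF); high ≡ AR ≥ 0.5 ≡ VAF ≥ 0.33.
  Multiple ITD calls classify on the maximum VAF — the question asked is
  "is a high-burden ITD clone present".
* **ELN 2017, gene-only.**  The cohort is cytogenetically normal by
  definition, so only the mutation rows of the ELN table are encoded:
  favorable = *NPM1*-mutated with ITD absent/low, or biallelic *CEBPA*;
  adverse = *NPM1*-wild-type with ITD-high, or mutated
  *RUNX1*/*ASXL1*/*TP53*; intermediate = the rest.  The guideline caveat
  that *RUNX1*/*ASXL1* should not count as adverse when a
  favorable-defining lesion co-occurs is applied by default; because
  published analyses are often ambiguous on this point the rule table is
  data (`ElnRules`) and the caveat is a switch.  *TP53* never yields.
* **DNMT3A-modified ELN.**  Any *DNMT3A* mutation reclassifies the
  patient as adverse; everything else is unchanged, so the modified and
  plain groupings differ exactly on *DNMT3A*-mutated patients.

## Clonal architecture

Clone fraction = 2·VAF clipped to [0, 1] (heterozygous autosomal
assumption; copy number and X-linked adjustment are out of scope).
Within a patient, calls with clone fraction ≥ `rel_threshold` × (largest
clone fraction) form the dominant tier — a singleton tier is *dominant*,
a multi-member tier *co-dominant* — and the rest are *subclones*.  The
default `rel_threshold = 0.67` puts a (0.47, 0.44) VAF pair in
co-dominance and a (0.45, 0.12) pair in dominant/subclone, matching the
qualitative architecture reported for this disease; because no published
cut-off exists the threshold is a parameter, and cohort-level subtype
counts should be read as threshold-dependent.  The rule is scale-free
(pure ratios), so uniform VAF attenuation (e.g. tumor purity) does not
change calls — except through the clip at clone fraction 1.0, which can
compress very high VAFs into ties.  Subtype keys
(`"dominant set | subclone set"`, tokens sorted) are permutation-
invariant but role-sensitive; prevalences are computed over patients
with ≥ 1 detectable mutation.

## Survival endpoints and estimators

Times are months from diagnosis (floating point); figures in years are a
presentation conversion only.

* **OS**: diagnosis → death, censored at last follow-up.
* **LFS**: CR1 → relapse or death (only for patients reaching CR1).
* **EFS**: diagnosis → induction failure, relapse, or death.  The
  induction-failure event for never-CR patients is placed at a
  configurable assessment time, default 2 months — an explicit
  interpretation, since EFS conventions vary.
* **Censor-at-HSCT**: either endpoint can be recensored at the
  transplant date for a transplant-free view; this is the complementary
  analysis to treating HSCT as a time-fixed covariate and carries the
  usual informative-censoring caveat.

Estimators are self-contained so that each is checkable by hand:
product-limit Kaplan–Meier with Greenwood variance (events precede
censorings at ties); the k-group log-rank test with hypergeometric
variance/covariance; and Cox proportional hazards on the Breslow partial
likelihood, fitted by Newton–Raphson with step-halving, convergence at
max |score| < 1e−8 within 50 iterations, Wald confidence intervals and
p-values plus a global likelihood-ratio test.  Breslow (not Efron) ties
were chosen because the brute-force risk-set product used as a test
oracle is then exact.  Monotone likelihood (perfect separation) is
flagged (|β̂| drifting beyond 10 on the log scale) rather than reported
as a converged estimate.  CR and CRi are pooled throughout.  No
multiple-testing correction is applied; subgroup p-values are
exploratory.

## Multistate outcome model

State graph entered at CR1: `CR1 → RELAPSE → DEATH_RELAPSE` and
`CR1 → TRM`, with TRM (death in remission) and death-after-relapse
absorbing.  Each transition k carries a cause-specific parametric hazard

    h_k(t) = λ0_k · γ_k · t^{γ_k − 1} · exp(β_kᵀ x),

exponential (γ = 1, default) or Weibull.  Covariates: age centered at
49 years, sex, log₁₀ WCC, genotype-category indicators (category 1
reference), and HSCT-at-CR1 as a time-fixed indicator — excluded from
the post-relapse transition by default since it encodes a CR1 strategy.
Pre-remission events (induction failure, refractory death) are not part
of the fitted likelihood: the model is post-remission decision support,
and the pre-CR funnel lives in the generator's CR-probability model.

Fitting maximizes each transition's cause-specific likelihood with the
other transitions censored.  The exponential fit is a joint Newton
iteration on (log λ0, β) (Poisson-likelihood structure, concave;
started from the closed-form no-covariate rate events/person-time);
Weibull adds log γ and refines from the exponential solution with
L-BFGS on the analytic gradient, standard errors from the observed
information (central differences of the gradient).  A transition with
zero observed events gets hazard 0 plus a warning flag instead of an
error.  The RELAPSE → DEATH clock restarts at relapse (semi-Markov);
for the default exponential family this choice is immaterial.

Occupancy curves P_s(t) solve the forward equations on the DAG: closed
form for exponential (including the a+b ≈ c degenerate limit), adaptive
quadrature (absolute tolerance 1e−10 per state) for Weibull, with
DEATH_RELAPSE computed as cumulative relapse incidence minus current
relapse occupancy so that conservation Σ_s P_s(t) = 1 holds to rounding
error for the closed form and to quadrature tolerance otherwise.
Strategy comparison evaluates P_CR1 (leukemia-free survival) under
hsct = 1 vs hsct = 0 at 24 and 60 months by default, plus the
death-in-relapse probability at the final horizon.  Default prediction
grid: 0–120 months, step 0.5.

The risk score used for evaluation is 1 − P_CR1(60 months) under the
patient's observed HSCT status.

## Concordance evaluation

Harrell's C (not a censoring-weighted variant): over ordered pairs where
the earlier time is an event (at tied times, event-vs-censored pairs
count with the event bearer failing first), the fraction ranked
correctly, half credit for tied scores.  The ELN baseline is the ordinal
encoding favorable = 0, intermediate = 1, adverse = 2; its many ties are
half-credited, which is exactly how an ordinal three-level predictor
should be scored.  Uncertainty: patient-level bootstrap (default 1,000
resamples, seeded); model-vs-baseline comparison: paired bootstrap with
a two-sided, +1-smoothed p-value on the concordance difference.  The
difference is reported both absolutely and relative to the baseline.
The train/validate workflow fits on the training cohort only and filters
refractory-stage HSCT patients (transplant without CR1) from the
validation cohort before scoring.

## Synthetic cohort generator

The generator is the package's ground-truth instrument; its defaults
describe a plausible young CN-AML cohort, not any specific patient
series.

* **Genotypes**: gene-by-gene Bernoulli marginals tilted by pairwise
  co-occurrence log-odds via a Gibbs sampler (50 burn-in sweeps,
  vectorized across patients).  A pairwise model suffices because only
  pairwise co-occurrence structure is being emulated.  Default marginals
  rank NPM1 > DNMT3A ≈ FLT3-ITD > the rest; with the default positive
  NPM1–DNMT3A–ITD interactions the realized frequencies land near
  NPM1 0.49, DNMT3A 0.34, FLT3-ITD 0.32 — field-typical values.  Known
  exclusivities (NPM1 vs CEBPA/RUNX1/TP53, IDH1 vs IDH2) get negative
  log-odds.  With all interactions zero the marginals are exact, which
  is what the fidelity tests check.
* **VAFs**: the first mutation drawn per patient is always dominant,
  truncated-normal (0.44, 0.05) clipped to [0, 1]; subsequent mutations
  are subclonal with probability 0.35 (0.70 for FLT3-ITD, which is
  predominantly subclonal) and then uniform on (0.08, 0.28) — below the
  co-dominance band of a typical 0.44 dominant clone; otherwise they
  join the dominant band.
* **Event histories**: ~95% receive induction; CR/CRi after first
  induction follows a logistic model (intercept 1.0 with negative WCC,
  age and adverse-category effects, giving a mid-60s% first-induction CR
  rate); 74% of failures reach CR1 via salvage; never-CR patients die at
  a refractory-course hazard.  From CR1, competing exponential clocks
  for relapse (λ0 = 0.008/month) and TRM (0.003/month), then death in
  relapse (0.05/month), each scaled by exp(βᵀx) with the same covariate
  vocabulary the fitted model uses; the defaults give ~60%/31% LFS and
  ~66%/34% OS at 2/5 years — plausible for this population.  HSCT at
  CR1 is assigned by risk-group policy (15/45/65% for modified-ELN
  favorable/intermediate/adverse) and acts as a time-fixed covariate
  from CR1 (true protective effect −0.7 on relapse, +0.9 on TRM);
  the transplant is *recorded* at a fixed 4-month delay only if the
  patient is still in remission then.  Administrative censoring at 120
  months.  A seed fully determines the cohort, bitwise.

**Limitations of the emulation.**  The default 4-month transplant delay
creates an immortal-time artifact: patients assigned HSCT who fail
within the delay carry the assignment's hazard but no recorded
transplant, so time-fixed-covariate fits on default-generated cohorts
attenuate the HSCT effect slightly.  Parameter-recovery tests therefore
use a zero-delay configuration, where the time-fixed model is correctly
specified.  More broadly, the generator has no time-varying hazards
unless Weibull is configured, no measurement error in VAFs, no loss to
follow-up before the administrative horizon, and no correlation between
genotype and WCC/age beyond what the hazard models induce — so passing
tests demonstrate the estimators and rules are correct under their own
assumptions, not that the model family captures real-world CN-AML
dynamics.

## Numerical and design choices

* Times are months; missing values are empty cells; floats serialize at
  shortest round-trip precision, so write→read is exact.
* Exponential transition fits converge at max |score| < 1e−10 (≤ 200
  iterations, step-halving); Cox at 1e−8 (≤ 50).
* Event/censoring ties: events first (risk sets include same-time
  censorings).
* The "machine-learning" predictor is concretized as the parametric
  cause-specific multistate model above — the simplest family that
  produces sediment curves and strategy deltas — behind a Results
  interface (`predict_occupancy`, `compare_strategies`, `risk_scores`)
  so richer learners can replace it without touching evaluation.
* Pipeline sub-seeds are SHA-256 hashes of `"{seed}:{stage}"` truncated
  below 2³¹, so adding a stage never shifts earlier stages' streams; the
  run manifest stores SHA-256 hashes of every artifact, making
  end-to-end determinism directly checkable.
* Patients lost to follow-up and administratively censored patients are
  treated identically (censoring at `last_followup`).
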