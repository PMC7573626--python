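cooccurrence_log_odds:
  DNMT3A|FLT3-ITD: 0.5
  IDH1|IDH2: -2.5
  NPM1|CEBPA: -2.0
  NPM1|DNMT3A: 0.9
  NPM1|FLT3-ITD: 0.7
  NPM1|RUNX1: -2.0
  NPM1|TP53: -1.5
covariate_effects:
  cr1_relapse:
    age_c: 0.01
    cat2: 0.3
    cat3: 0.5
    cat4: 0.6
    cat5: 0.8
    hsct: -0.7
    log10_wcc: 0.4
  cr1_trm:
    age_c: 0.03
    hsct: 0.9
  refractory_death: {}
  relapse_death:
    cat5: 0.4
    log10_wcc: 0.3
cr_probability:
  age_c: -0.01
  cat2: -0.1
  cat3: -0.2
  cat4: -0.5
  cat5: -0.4
  intercept: 1.0
  log10_wcc: -0.35
followup_max: 120.0
gene_freqs:
  ASXL1: 0.04
  CEBPA: 0.08
  DNMT3A: 0.22
  FLT3-ITD: 0.22
  FLT3-TKD: 0.1
  IDH1: 0.08
  IDH2: 0.12
  KRAS: 0.04
  NPM1: 0.4
  NRAS: 0.12
  RUNX1: 0.06
  TET2: 0.1
  TP53: 0.02
  WT1: 0.08
hsct_delay: 4.0
hsct_policy:
  adverse: 0.65
  favorable: 0.15
  intermediate: 0.45
n_patients: 459
p_induction: 0.95
p_salvage_cr: 0.74
p_subclone: 0.35
p_subclone_overrides:
  FLT3-ITD: 0.7
seed: 0
transition_hazards:
  cr1_relapse: 0.008
  cr1_trm: 0.003
  refractory_death: 0.08
  relapse_death: 0.05
vaf_dominant:
- 0.44
- 0.05
vaf_subclone:
- 0.08
- 0.28
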