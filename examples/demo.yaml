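# Two-sex synthetic demo: three causal biomarkers, block missingness.
seed: 7
simulate:
  n_persons: 2000
  n_continuous: 12
  n_categorical: 2
  signal_effects:
    lab_01: 2.5    # protective: +2.5 years of life per SD
    lab_02: -2.5   # harmful
    lab_03: 1.8
  noise_sd: 2.0
  exam_age_range: [66.0, 74.0]
  exam_years: [1998, 2005]
  missing_rates:
    laboratory: 0.15
    questionnaire: 0.3
  frac_accidental_death: 0.02
  frac_medicated: 0.03
  male_fraction: 0.5
impute:
  method: mice     # or: filter
  n_iterations: 3
model:
  preset:
    n_estimators: 300
    early_stopping_rounds: 30
bioage:
  avg_age: 80.0    # region-less synthetic cohort: constant reference expectancy
report: true
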