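# Desk-scale smoke configuration: completes in seconds on one CPU.
# Uses a smaller population and bootstrap; regression trimmed to covariates
# with enough events at this scale.
seed: 0
B: 100
pop_size: 40000
probability_design:
  n_strata: 6
  psus_per_stratum: 8
  sample_psus_per_stratum: 4
  respondents_per_psu: 100
optin_design:
  selection_intercept: -2.2
# uncalibrated intercepts: non-rare outcomes so the trimmed regression has
# enough events at this sample size
outcome_intercepts: {heroin: -3.6, imf: -3.9}
family:
  - [outcome, either, past_year]
  - [outcome, either, past_month]
  - [outcome, heroin, past_year]
  - [outcome, imf, past_year]
  - [share, sex, female]
  - [share, education, college graduate]
regression_covariates: [sex, cigarette_use, stimulant_py, benzo_py, employment]
write_surveys: false
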