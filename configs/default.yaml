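# Shipped default run configuration (illustrative effect sizes; see
# docs/methods.md §5). Any omitted key falls back to the built-in default:
# population of 500,000; probability arm 20 strata x 25 PSUs (5 sampled,
# 300 respondents each); opt-in panel ~30,000 respondents raked to
# age/sex/race/education/income; B = 2000; alpha = 0.05; m = 43.
seed: 0
B: 2000
alpha: 0.05
resample_unit: psu
family: default
write_surveys: true
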