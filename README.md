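# crossprev

Cross-survey prevalence comparison for substance-use surveillance: compare
design-weighted prevalence estimates of rare outcomes (past-year heroin use,
illicitly manufactured fentanyl use, and either) between a **probability
household survey** (stratified, clustered, nonresponse-adjusted weights) and
an **opt-in online panel** (self-selected, raking-calibrated weights) — two
designs that cannot be pooled into one model.

It is written for epidemiologists and survey methodologists who need to (a)
quantify how much two differently designed surveys of the same population
disagree, with honest simultaneous uncertainty, and (b) validate that
machinery on synthetic data with known truth before touching restricted
microdata.

## What it computes

* **Design-based prevalence** — Hajek ratio p̂ = Σwᵢyᵢ/Σwᵢ with
  Taylor-linearized ultimate-cluster variance
  (Σₕ [nₕ/(nₕ−1)] Σⱼ (z_hj − z̄ₕ)² / (Σw)², z_hj the per-PSU score totals)
  and logit-transformed confidence intervals suited to sub-1% prevalences.
* **Bootstrap differences** — each survey is independently resampled with
  replacement B times (PSUs within strata for the probability design,
  respondents for the panel); the difference is summarized by its replicate
  mean with percentile intervals and **Bonferroni-corrected** percentile
  intervals at level 1 − α/m (α = 0.05, m = 43 → 99.88% cCIs).
* **Survey-weighted logistic regression** — IRLS solution of
  Σ wᵢxᵢ(yᵢ − πᵢ(β)) = 0 with ultimate-cluster sandwich covariance,
  adjusted odds ratios, generalized VIF screening (cutoff 5), and
  delta-method **average marginal effects**.
* **Synthetic dual-survey generation** — a realized latent population with
  configurable covariates and per-outcome logistic models, a two-stage
  probability arm with logistic nonresponse, and an opt-in arm with
  (optionally outcome-dependent) self-selection plus raking, so every
  estimator is testable against exhaustive population counts.

See `docs/methods.md` for the full statistical account and
`docs/data_dictionary.md` for the harmonized column dictionary.

## Worked example

```python
from crossprev import pipeline

cfg = pipeline.config_from_yaml("configs/smoke.yaml")   # desk-scale config
res = pipeline.run_pipeline(cfg, "smoke_out")

est = res["estimates"]
print(est[est.quantity == "either:past_year"]
      [["survey", "pct", "ci_low_pct", "ci_high_pct", "n_unweighted"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

row = res["differences"].set_index("quantity").loc["either:past_year"]
print(f"difference (panel - probability): {row.diff_point:.3f} pp "
      f"[{row.ci_level_percent}% cCI {row.cci_low:.3f}, {row.cci_high:.3f}], "
      f"B={int(row.B)}, m={int(row.m)}")
print(f"population truth: {res['truth_pct']['either:past_year']:.3f}%")
```

prints (seed 0):

```
     survey   pct  ci_low_pct  ci_high_pct  n_unweighted
probability 1.788       1.384        2.306          1789
      panel 4.510       3.933        5.167          4562
difference (panel - probability): 2.641 pp [99.17% cCI 1.654, 3.721], B=100, m=6
population truth: 2.415%
```

Reading it: the probability survey's weighted past-year either-use estimate
(1.79%, design-based 95% CI) is close to the true population value (2.42%
realized; the gap here is one draw's sampling noise), while the panel —
whose synthetic self-selection favors people who use — lands at 4.51% even
after raking. The bootstrap difference of 2.64 percentage points, with a
Bonferroni-corrected interval for this 6-quantity family excluding zero,
flags the design-driven disagreement. The same run writes Table-style CSVs
(`estimates.csv`, `differences.csv`, `regression.csv`, `ame.csv`,
`recovery.csv`) and a `manifest.json` recording every decision switch; the
shipped full-scale configuration (`configs/default.yaml`, B = 2000, m = 43,
population 500,000) operates in the sub-1% prevalence regime.

The same pipeline is available from a shell:

```sh
crossprev run --config configs/smoke.yaml --out smoke_out
crossprev generate --seed 1 --out data_dir      # surveys as CSV + JSON sidecar
```

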