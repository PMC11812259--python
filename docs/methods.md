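# Methods

`crossprev` implements a cross-survey comparison of rare-outcome prevalence
between two surveys of the same target population that cannot be pooled: a
stratified, clustered probability household survey and an opt-in online
panel. This note documents the statistical procedures, the synthetic data
model they are validated against, the numerical conventions, and the design
choices that were genuinely open.

## 1. Design-based prevalence estimation

For an analysis cell defined by an indicator `y` (e.g. past-year use of
either heroin or illicitly manufactured fentanyl), the point estimate is the
Hajek ratio

    p̂ = Σ wᵢ yᵢ / Σ wᵢ,

with analytic weights `wᵢ`. Variance is Taylor-linearized under the
**ultimate-cluster, with-replacement-first-stage** approximation: with
per-PSU score totals `z_hj = Σ_{i∈hj} wᵢ (yᵢ − p̂)`,

    var(p̂) = Σ_h [n_h/(n_h−1)] Σ_j (z_hj − z̄_h)² / (Σ wᵢ)².

This is the de facto variance convention for national household-survey
designs and requires ≥ 2 sampled PSUs per stratum; a singleton-PSU stratum
is an error, never silently collapsed. The opt-in panel is analyzed as a
single-stage design with each respondent its own sampling unit and
calibrated weights. No finite-population corrections are applied; as a
consequence a census-design dataset reproduces the population proportion
exactly but still reports a positive (spurious) sampling variance — the
with-replacement approximation's known behavior, accepted here because the
estimators target small sampling fractions.

Confidence intervals are **logit-transformed**: a normal interval for
`log(p/(1−p))` with delta-method SE `se/(p(1−p))`, back-transformed. At the
sub-1% prevalences this package targets, symmetric Wald intervals can cross
zero; the logit interval cannot. `p̂ ∈ {0, 1}` degenerates to a point
interval and is flagged in the output metadata. The interval method is
recorded in every estimate because published survey tables rarely state it.

## 2. Cross-survey bootstrap differences

The two designs cannot be combined in one model, so differences are
estimated by independently resampling each survey with replacement B times
(default B = 2000), recomputing the weighted estimate on every replicate,
and forming the replicate-wise difference, signed **panel minus probability
survey**. The reported point estimate is the mean of the B differences; the
plain difference of the original-sample estimates is emitted alongside for
comparison.

Resampling units: **PSUs within strata** for the probability survey (the
unit the variance model treats as independent) and **respondents** for the
panel. A PSU drawn k times contributes k weight-preserving copies. The unit
is a config switch (`psu` | `respondent`) stamped into the run manifest,
because descriptions of bootstrap procedures for complex surveys frequently
leave it unstated. Weights are carried into replicates unmodified —
per-replicate re-raking is exposed but off by default, keeping B = 2000
cheap; the no-re-raking choice slightly understates the panel's calibration
variability.

Intervals are **empirical percentile intervals** — inverse empirical CDF
with linear interpolation (numpy's default quantile rule, fixed and
documented) — at level `1 − α` and, for m simultaneous comparisons, at the
Bonferroni-corrected level `1 − α/m`. With α = 0.05 and the default
43-quantity family, `α_c = 0.05/43 ≈ 0.0012` (conventionally printed
0.0011), i.e. 99.88% corrected intervals. The corrected interval contains
the uncorrected one by construction, asserted on every call.

Replicate seeds follow a fixed protocol: replicate b of survey s uses
`SeedSequence([seed, b, s])`, making the replicate stream independent of B
and bit-reproducible. Replicates on which an estimate is undefined are
excluded and counted; more than 5% exclusions aborts the run.

Per-replicate estimates are computed from per-unit weighted totals
(`Σ wy`, `Σ w` per PSU or respondent), which is algebraically identical to
rebuilding each replicate dataset but runs in O(units); the test suite
verifies replicate-for-replicate agreement with a literal
resample-rebuild-estimate loop under the same seed protocol.

## 3. Survey-weighted logistic regression

Coefficients solve the weighted score equations
`Σ wᵢ xᵢ (yᵢ − πᵢ(β)) = 0` by IRLS, converging when the max absolute score
falls below 1e−8 or the relative deviance change below 1e−10 (max 100
iterations). Complete or quasi-complete separation is detected as a
diverging standardized coefficient (|β·sd| > 15) and raised as an explicit
error: sparse cells are the analyst's signal to collapse categories, not
something to penalize away. The covariance is the linearized sandwich with
the same ultimate-cluster rule as §1 (per-PSU score totals, stratum
centering; per-respondent units for the panel). Adjusted odds ratios are
`exp(β)` with normal-quantile Wald intervals; the normal (rather than
design-df t) convention is recorded in the fit manifest.

Multicollinearity is screened with the Fox–Monette **generalized VIF** on
the weighted correlation matrix of the dummy-coded design matrix
(`GVIF = det(R₁₁)det(R₂₂)/det(R)`), which reduces to `1/(1−R²)` for
single-column covariates; values above 5 are flagged. Rank deficiency is an
error naming the aliased columns (pivoted QR).

**Average marginal effects** for level ℓ of covariate X counterfactually set
X←ℓ and X←reference for every record and report the weighted mean difference
in predicted probability; SEs are by the delta method through the
design-based covariance (gradient `Σ wᵢ[π₁(1−π₁)x₁ − π₀(1−π₀)x₀]/Σ wᵢ`),
chosen over bootstrap SEs for determinism.

All of §1–§3 are invariant to rescaling all weights by a positive constant;
this is property-tested.

## 4. The synthetic dual-survey generator

The generator realizes an explicit population table so every estimator can
be checked against exhaustive counts.

* **Covariates** are categorical with configurable marginals, drawn
  independently by default; an optional pairwise log-odds tilt induces
  association between a covariate level and a binary covariate. With tilts
  off, the exact model-implied prevalence is computed by enumerating the
  joint of only the covariates carrying outcome coefficients (the rest
  integrate out), and intercepts can be calibrated by root-finding to hit a
  target marginal prevalence exactly.
* **Outcomes**: past-year heroin and past-year IMF use are independent
  Bernoulli draws given covariates from per-outcome logistic models;
  association between the two outcomes arises through shared covariates.
  Recency within past-year users is a two-level split (past-month vs 2–12
  months) with a per-outcome split probability. "Either use" is the
  elementwise maximum of the two recencies. A past-month misclassification
  knob (default 0) models the "4 weeks" vs "past 30 days" wording
  difference between survey instruments.
* **Probability arm**: persons are partitioned into strata × PSU cells
  (random partition by default, so intra-cluster correlation is nil unless
  induced through the partition rule); PSUs and persons are drawn without
  replacement; base weight = inverse inclusion probability. Nonresponse is
  a single-stage logistic propensity; respondent weights are multiplied by
  the inverse response rate within adjustment cells formed by crossing the
  propensity model's covariates, which redistributes the nonrespondents'
  weight mass exactly (cells emptied of respondents fall back to a global
  ratio adjustment). Real household-survey weighting is far more elaborate;
  only the weights' downstream behavior matters for validating the
  estimators.
* **Opt-in arm**: each person joins independently with probability
  `expit(selection model)`; the selection model may depend on the outcome
  itself, emulating differential participation/disclosure — the mechanism
  that lets the panel's weighted prevalence exceed the population value even
  after calibration, since raking cannot correct selection on the outcome.
  Respondents are split into two pooled waves. Weights start uniform and
  are **raked** (iterative proportional fitting) to exact population
  category counts until every margin share is within tolerance (default
  1e−8, max 100 cycles); an absent margin category is a named
  non-convergence error. Margins already satisfied return the weights
  unchanged.

**What passing tests do and do not show.** The generator reproduces the
structural features the estimators rely on — clustered weighted sampling,
informative nonresponse, outcome-informative self-selection, calibration —
but not real-survey phenomena such as measurement/wording effects beyond the
single misclassification knob, multi-stage weighting systems, panel
conditioning, or item nonresponse beyond the blank-cigarette rule. Passing
calibration tests therefore validates the *estimators under their assumed
designs*, not the substantive comparability of any two real surveys.

## 5. Default configuration and problem sizes

The shipped default config is labeled **illustrative**: no generative facts
about the real population are known beyond published marginal results, so
effect sizes are chosen to be plausible and the intercepts are calibrated so
the model-implied population past-year prevalence is 0.39% for heroin and
0.52% for either-use, with the panel's self-selection tilt (log-odds
ln 2.02 on either-use) pushing its weighted estimate to ≈ 1%, the
small-proportion regime the method targets. Population 500,000; probability
arm 20 strata × 25 PSUs, 5 sampled PSUs/stratum × 300 persons (≈ 22,500
respondents after ≈ 75% response); panel ≈ 30,000 respondents raked to age,
sex, race/ethnicity, education and income margins; B = 2000; α = 0.05;
m = 43 (9 outcome cells + 34 characteristic shares — a reconstructed family,
flagged as such in the run manifest).

Validation studies run at desk scale chosen to balance Monte-Carlo
resolution against runtime: 200 null families and 200 recovery experiments
(B = 500, ~5,000 respondents per survey, m = 10 quantities spanning shares
of 5–50% plus a 1–2% outcome), 300 regression replicates at n = 2,000, and
500 draws for CI-coverage checks. Monte-Carlo error bands (3 SEs) are
reported with every study.

## 6. Numerical conventions and degenerate inputs

* Quantiles: linear-interpolation inverse empirical CDF, everywhere.
* Logistic probabilities clipped at 1e−12 inside the IRLS deviance only.
* Raking tolerance is on margin *shares* and on the weight total; totals of
  different margins must agree to 1e−6 relative.
* Recency order is NONE < MONTHS_2_12 < PAST_MONTH; past-month without
  past-year is a data-consistency error naming the respondent.
* Blank cigarette frequency → "not at all" (idempotent); race collapses to
  four modeling levels; heavy alcohol: ≥ 15 drinks/week (men), ≥ 8 (women).
* All CSVs are written with pandas' default float representation (shortest
  round-trip), making artifacts byte-identical across reruns of one config.

## 7. Known limitations

* No replicate-weight (BRR/jackknife) variance machinery, no
  finite-population corrections, no BCa or studentized bootstrap intervals,
  no Firth penalization, no pooled-survey modeling.
* The sub-1% outcome regime at desk-scale sample sizes leaves few events per
  covariate level; the regression defaults require the default sample sizes
  (≈ 20k+) to stay away from separation.
* Percentile intervals at extreme corrected levels (e.g. 99.88%) lean on
  the far tails of B replicates; B should be ≥ a few thousand when m is
  large. The family-wise calibration study measures exactly this at m = 10,
  B = 500.
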