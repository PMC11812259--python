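"""Simulation studies that calibrate the pipeline against known truth.

Each study generates synthetic dual-survey data with known population truth,
runs the real estimation / comparison / regression machinery, and measures
frequentist operating characteristics (family-wise error, interval coverage,
bias).  They back the test suite and the reproduction script; problem sizes
are arguments so the studies scale from desk checks to larger batches.

Seed protocol: study unit ``r`` derives child seeds ``SeedSequence([seed, r,
k])`` for its population (k=0), survey draws (k=1, 2), and an integer
bootstrap master seed (k=3), so units are independent and reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

from . import compare, synthetic_data
from .dataset import OPTIN_PANEL, SurveyDesignSpec
from .regression import fit_weighted_logit


def _unit_seed(seed: int, r: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, r, k])


def _boot_seed(seed: int, r: int) -> int:
    return int(_unit_seed(seed, r, 3).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# null calibration: family-wise error of the corrected intervals


NULL_SHARE_PROBS = (0.05, 0.08, 0.10, 0.15, 0.20, 0.25, 0.30, 0.40, 0.50)


def _null_truth(pop_size: int, outcome_prevalence: float) -> synthetic_data.PopulationTruth:
    covariates = {
        f"q{i}": {"yes": p, "no": 1.0 - p} for i, p in enumerate(NULL_SHARE_PROBS)
    }
    return synthetic_data.PopulationTruth(
        pop_size=pop_size,
        covariates=covariates,
        outcome_models={
            "heroin": {"intercept": float(logit(outcome_prevalence))},
            "imf": {"intercept": -50.0},
        },
        recency_split={"heroin": 0.6, "imf": 0.5},
    )


def _null_indicators() -> dict:
    ind = {
        f"q{i}": (lambda df, i=i: (df[f"q{i}"] == "yes").to_numpy())
        for i in range(len(NULL_SHARE_PROBS))
    }
    ind["either:past_year"] = lambda df: (df["either_recency"] != "none").to_numpy()
    return ind


def null_familywise_error(
    n_families: int = 200,
    B: int = 500,
    pop_size: int = 50_000,
    sampling_rate: float = 0.1,
    m: int = 10,
    alpha: float = 0.05,
    outcome_prevalence: float = 0.02,
    seed: int = 0,
) -> dict:
    """Family-wise error of Bonferroni-corrected bootstrap intervals under the null.

    Each family draws two opt-in samples (~``pop_size * sampling_rate``
    respondents each) from one shared population, so every quantity's true
    cross-survey difference is exactly zero.  A family errs when at least one
    of its m corrected intervals excludes 0.  Returns the error rate and its
    Monte-Carlo SE.
    """
    truth = _null_truth(pop_size, outcome_prevalence)
    design = SurveyDesignSpec(
        kind=OPTIN_PANEL,
        selection_model={"_intercept": float(logit(sampling_rate))},
        label="panel",
    )
    indicators = _null_indicators()
    if m != len(indicators):
        raise ValueError(f"this study defines {len(indicators)} quantities, not m={m}")
    errors = 0
    for fam in range(n_families):
        population, _ = synthetic_data.generate_population(truth, _unit_seed(seed, fam, 0))
        a = synthetic_data.draw_optin_sample(population, design, _unit_seed(seed, fam, 1))
        b = synthetic_data.draw_optin_sample(population, design, _unit_seed(seed, fam, 2))
        diffs, _ = compare.bootstrap_differences(
            a, b, indicators, B=B, seed=_boot_seed(seed, fam)
        )
        family_err = False
        for name in diffs.columns:
            de = compare.summarize_difference(diffs[name].to_numpy(), alpha=alpha, m=m)
            if de.cci_low > 0.0 or de.cci_high < 0.0:
                family_err = True
                break
        errors += family_err
    rate = errors / n_families
    return {
        "n_families": n_families,
        "B": B,
        "m": m,
        "alpha": alpha,
        "familywise_error_rate": rate,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_families)),
    }


# ---------------------------------------------------------------------------
# recovery: a true 0.5-percentage-point cross-survey difference


def difference_recovery(
    n_experiments: int = 200,
    B: int = 500,
    pop_size: int = 50_000,
    sampling_rate: float = 0.1,
    prevalence_a: float = 0.010,
    prevalence_b: float = 0.015,
    m: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Coverage and bias of the corrected difference interval under a true gap.

    Survey A samples a population with either-use prevalence ``prevalence_a``
    and survey B one with ``prevalence_b`` (default gap 0.5 percentage
    points).  Per experiment the truth is the *realized* population
    difference; coverage counts experiments whose corrected interval (level
    ``1 - alpha/m``) contains it, and bias averages the bootstrap-mean point
    estimate minus the truth.
    """
    truths = [
        _null_truth(pop_size, prevalence_a),
        _null_truth(pop_size, prevalence_b),
    ]
    design = SurveyDesignSpec(
        kind=OPTIN_PANEL,
        selection_model={"_intercept": float(logit(sampling_rate))},
        label="panel",
    )
    indicator = {"either:past_year": lambda df: (df["either_recency"] != "none").to_numpy()}
    covered = 0
    errors = np.empty(n_experiments)
    for r in range(n_experiments):
        samples, deltas = [], []
        for s, truth in enumerate(truths):
            population, realized = synthetic_data.generate_population(
                truth, _unit_seed(seed, r, 2 * s)
            )
            samples.append(
                synthetic_data.draw_optin_sample(
                    population, design, _unit_seed(seed, r, 2 * s + 1)
                )
            )
            deltas.append(realized["either"]["past_year"])
        true_delta = 100.0 * (deltas[1] - deltas[0])
        diffs, _ = compare.bootstrap_differences(
            samples[0], samples[1], indicator, B=B, seed=_boot_seed(seed, r)
        )
        de = compare.summarize_difference(
            100.0 * diffs["either:past_year"].to_numpy(), alpha=alpha, m=m
        )
        covered += de.cci_low <= true_delta <= de.cci_high
        errors[r] = de.diff_point - true_delta
    alpha_c = alpha / m
    return {
        "n_experiments": n_experiments,
        "B": B,
        "m": m,
        "nominal_coverage": 1.0 - alpha_c,
        "coverage": covered / n_experiments,
        "coverage_mc_se": float(np.sqrt(alpha_c * (1 - alpha_c) / n_experiments)),
        "mean_bias_pct": float(errors.mean()),
        "bias_mc_se": float(errors.std(ddof=1) / np.sqrt(n_experiments)),
    }


# ---------------------------------------------------------------------------
# regression calibration: Wald coverage of a nonzero coefficient


def regression_wald_coverage(
    n_reps: int = 300,
    n: int = 2000,
    beta0: float = -1.2,
    beta_x: float = 0.8,
    seed: int = 0,
) -> dict:
    """95% Wald coverage of a true nonzero slope under the generating model.

    Unit weights and respondent-level units: each replicate simulates a
    binary predictor (p = 0.5) and a Bernoulli outcome from the logistic
    model, fits the survey-weighted estimator, and checks the Wald interval.
    """
    import pandas as pd

    from .dataset import SurveyDataset

    covered = 0
    z = 1.959963984540054
    for r in range(n_reps):
        rng = np.random.default_rng(_unit_seed(seed, r, 0))
        x = rng.integers(0, 2, n)
        y = (rng.random(n) < expit(beta0 + beta_x * x)).astype(float)
        df = pd.DataFrame(
            {"y": y, "x": np.where(x == 1, "yes", "no"), "weight": np.ones(n)}
        )
        ds = SurveyDataset(data=df, kind=OPTIN_PANEL, weight_col="weight", label="sim")
        model = fit_weighted_logit(ds, "y", ["x"], {"x": "no"}, compute_vifs=False)
        j = model.terms.index(("x", "yes"))
        se = float(np.sqrt(model.cov[j, j]))
        covered += abs(model.beta[j] - beta_x) <= z * se
    return {
        "n_reps": n_reps,
        "n": n,
        "beta_x": beta_x,
        "coverage": covered / n_reps,
        "mc_se": float(np.sqrt(0.95 * 0.05 / n_reps)),
    }
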