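"""End-to-end orchestration: generate -> harmonize -> estimate -> compare -> regress.

A :class:`RunConfig` fixes one master seed, the population truth, both survey
designs, the comparison family (m quantities entering the Bonferroni
correction), the bootstrap replicate count B, and the regression formula.
:func:`run_pipeline` executes every stage, writes Table-style CSV reports
plus a JSON manifest, and is byte-reproducible under a fixed config.

Every random draw flows from the master seed through a fixed child-seed
scheme: stage k uses ``SeedSequence([seed, k])`` (k = 0 population,
1 probability sample, 2 opt-in panel), and the bootstrap master seed is an
integer derived from ``SeedSequence([seed, 3])``.

The default configuration is illustrative: effect sizes are chosen so the
population's past-year either-use prevalence is ~0.5% and the panel's
self-selection tilts its weighted estimate to ~1%, the small-proportion
regime national substance-use surveillance operates in.  The default
43-quantity comparison family is likewise a reconstruction, not a copy of
any survey's published family.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import compare as compare_mod
from . import estimation, harmonize, regression, synthetic_data
from .dataset import OPTIN_PANEL, PROBABILITY_CLUSTERED, SurveyDataset, SurveyDesignSpec, _jsonable


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# default study configuration


def default_truth(pop_size: int = 500_000, calibrate: bool = True) -> synthetic_data.PopulationTruth:
    """Illustrative population truth mirroring the harmonized covariate dictionary."""
    covariates = {
        "age_group": {"18-25": 0.14, "26-34": 0.16, "35-49": 0.25, "50-64": 0.24, "65+": 0.21},
        "sex": {"male": 0.49, "female": 0.51},
        "race_ethnicity": {
            "non-Hispanic White": 0.60,
            "non-Hispanic Black": 0.12,
            "Hispanic": 0.17,
            "Asian": 0.06,
            "Native American": 0.01,
            "Native Hawaiian": 0.002,
            "Multiple races": 0.025,
            "Other": 0.013,
        },
        "income": {"<$50,000": 0.38, "$50,000-$74,999": 0.17, ">=$75,000": 0.45},
        "education": {"no college degree": 0.62, "college graduate": 0.38},
        "marital": {"married": 0.50, "never married": 0.28, "other": 0.22},
        "employment": {"worked past week": 0.62, "no past-week employment": 0.38},
        "insurance": {"private": 0.55, "not private": 0.45},
        "cigarette_use": {"every day": 0.11, "some days": 0.04, "not at all": 0.84, "missing": 0.01},
        "cannabis_py": {"yes": 0.18, "no": 0.82},
        "stimulant_py": {"yes": 0.03, "no": 0.97},
        "benzo_py": {"yes": 0.02, "no": 0.98},
        "heavy_alcohol": {"yes": 0.06, "no": 0.94},
        "moud_py": {"yes": 0.005, "no": 0.995},
        "hospitalization_py": {"yes": 0.08, "no": 0.92},
        "health": {"Fair/Poor": 0.15, "Good": 0.30, "Very Good": 0.35, "Excellent": 0.20},
    }
    outcome_models = {
        "heroin": {
            "intercept": -6.3,
            "effects": {
                "stimulant_py": {"yes": 2.6},
                "benzo_py": {"yes": 1.6},
                "moud_py": {"yes": 3.0},
                "cigarette_use": {"not at all": -1.3},
                "sex": {"female": -0.6},
                "employment": {"worked past week": -0.5},
                "insurance": {"not private": 0.8},
            },
        },
        "imf": {
            "intercept": -6.7,
            "effects": {
                "stimulant_py": {"yes": 2.8},
                "benzo_py": {"yes": 1.5},
                "moud_py": {"yes": 2.8},
                "cigarette_use": {"not at all": -1.2},
                "sex": {"female": -0.7},
                "employment": {"worked past week": -0.4},
                "insurance": {"not private": 0.7},
            },
        },
    }
    truth = synthetic_data.PopulationTruth(
        pop_size=pop_size,
        covariates=covariates,
        outcome_models=outcome_models,
        recency_split={"heroin": 0.65, "imf": 0.45},
    )
    if calibrate:
        # population past-year heroin 0.39%, and either-use 0.52% via the IMF intercept
        truth = synthetic_data.calibrate_intercept(truth, "heroin", 0.0039)
        truth = synthetic_data.calibrate_intercept(
            truth, "imf", 0.0052, quantity=("either", "past_year")
        )
    return truth


def default_probability_design(
    n_strata: int = 20,
    psus_per_stratum: int = 25,
    sample_psus_per_stratum: int = 5,
    respondents_per_psu: int = 300,
) -> SurveyDesignSpec:
    return SurveyDesignSpec(
        kind=PROBABILITY_CLUSTERED,
        n_strata=n_strata,
        psus_per_stratum=psus_per_stratum,
        sample_psus_per_stratum=sample_psus_per_stratum,
        respondents_per_psu=respondents_per_psu,
        nonresponse_model={
            "_intercept": 1.4,
            "employment": {"worked past week": -0.3},
            "age_group": {"18-25": -0.4, "26-34": -0.2},
        },
        label="probability",
    )


def default_optin_design(selection_intercept: float = -2.75) -> SurveyDesignSpec:
    return SurveyDesignSpec(
        kind=OPTIN_PANEL,
        selection_model={
            "_intercept": selection_intercept,
            "education": {"college graduate": 0.35},
            "race_ethnicity": {"non-Hispanic White": 0.20},
            "employment": {"worked past week": -0.25},
            # differential participation/disclosure by people who use: the
            # mechanism that makes the panel's weighted prevalence exceed the
            # population value (raking cannot remove selection on the outcome)
            "either_recency": {"past_month": 0.703, "months_2_12": 0.703},
        },
        raking_margins=["age_group", "sex", "race_ethnicity", "education", "income"],
        label="panel",
    )


OUTCOME_CELLS = [
    (outcome, recency)
    for outcome in ("heroin", "imf", "either")
    for recency in ("past_year", "past_month", "months_2_12")
]


def default_family() -> list[tuple]:
    """Reconstructed 43-quantity comparison family: 9 outcome cells + 34 shares."""
    family: list[tuple] = [("outcome", o, r) for o, r in OUTCOME_CELLS]
    shares: list[tuple[str, str]] = []
    shares += [("age_group", lvl) for lvl in ("18-25", "26-34", "35-49", "50-64", "65+")]
    shares += [("sex", "female"), ("sex", "male")]
    shares += [
        ("race4", lvl)
        for lvl in (
            "non-Hispanic White",
            "non-Hispanic Black",
            "Hispanic",
            "another non-Hispanic race",
        )
    ]
    shares += [("income", lvl) for lvl in ("<$50,000", "$50,000-$74,999", ">=$75,000")]
    shares += [("education", "college graduate")]
    shares += [("marital", lvl) for lvl in ("married", "never married", "other")]
    shares += [("employment", "worked past week"), ("employment", "no past-week employment")]
    shares += [("insurance", "not private")]
    shares += [("cigarette_use", lvl) for lvl in ("every day", "some days", "not at all")]
    shares += [
        (cov, "yes")
        for cov in (
            "cannabis_py",
            "stimulant_py",
            "benzo_py",
            "heavy_alcohol",
            "moud_py",
            "hospitalization_py",
        )
    ]
    shares += [("health", lvl) for lvl in ("Fair/Poor", "Good", "Very Good", "Excellent")]
    family += [("share", cov, lvl) for cov, lvl in shares]
    return family


DEFAULT_REGRESSION_COVARIATES = [
    "age_group",
    "sex",
    "race4",
    "income",
    "education",
    "marital",
    "employment",
    "insurance",
    "cigarette_use",
    "cannabis_py",
    "stimulant_py",
    "benzo_py",
    "heavy_alcohol",
    "moud_py",
    "hospitalization_py",
    "health",
]

DEFAULT_REFERENCE_LEVELS = {
    "age_group": "18-25",
    "sex": "male",
    "race4": "non-Hispanic White",
    "income": "<$50,000",
    "education": "no college degree",
    "marital": "married",
    "employment": "no past-week employment",
    "insurance": "private",
    "cigarette_use": "every day",
    "cannabis_py": "no",
    "stimulant_py": "no",
    "benzo_py": "no",
    "heavy_alcohol": "no",
    "moud_py": "no",
    "hospitalization_py": "no",
    "health": "Excellent",
}


@dataclass
class RunConfig:
    """One seeded end-to-end run specification."""

    seed: int
    truth: synthetic_data.PopulationTruth
    design_probability: SurveyDesignSpec
    design_optin: SurveyDesignSpec
    family: list[tuple]
    m: int
    alpha: float = 0.05
    B: int = 2000
    resample_unit: str = "psu"  # bootstrap unit for the probability survey
    regression_outcome: tuple[str, str] = ("either", "past_year")
    regression_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_REGRESSION_COVARIATES))
    reference_levels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS))
    ci_level: float = 0.95
    write_surveys: bool = True

    def __post_init__(self) -> None:
        if self.m != len(self.family):
            raise ConfigError(
                f"m = {self.m} but the comparison family lists {len(self.family)} quantities"
            )
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if self.resample_unit not in ("psu", "respondent"):
            raise ConfigError("resample_unit must be 'psu' or 'respondent'")
        known = set(self.truth.covariates) | {"race4"}
        for q in self.family:
            if q[0] == "share" and q[1] not in known:
                raise ConfigError(f"family references unknown covariate {q[1]!r}")


def default_config(seed: int = 0, **overrides: Any) -> RunConfig:
    family = default_family()
    cfg = dict(
        seed=seed,
        truth=default_truth(),
        design_probability=default_probability_design(),
        design_optin=default_optin_design(),
        family=family,
        m=len(family),
    )
    cfg.update(overrides)
    return RunConfig(**cfg)


def config_from_yaml(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a run config from YAML, overlaying the shipped defaults.

    Supported keys: seed, alpha, B, resample_unit, pop_size, probability_design
    (field overrides), optin_design (field overrides), family ("default" or a
    list of [kind, a, b] triples), m, regression_covariates, write_surveys.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if seed is None:
        seed = int(raw.get("seed", 0))
    intercepts = raw.get("outcome_intercepts")
    truth = default_truth(pop_size=int(raw.get("pop_size", 500_000)), calibrate=intercepts is None)
    if intercepts:
        models = {k: dict(v) for k, v in truth.outcome_models.items()}
        for outcome, b0 in intercepts.items():
            models[outcome] = {**models[outcome], "intercept": float(b0)}
        truth = dataclasses.replace(truth, outcome_models=models)
    dp = default_probability_design(**raw.get("probability_design", {}))
    do_kwargs = raw.get("optin_design", {})
    do = default_optin_design(**do_kwargs)
    if raw.get("family", "default") == "default":
        family = default_family()
    else:
        family = [tuple(q) for q in raw["family"]]
    kwargs: dict[str, Any] = dict(
        seed=seed,
        truth=truth,
        design_probability=dp,
        design_optin=do,
        family=family,
        m=int(raw.get("m", len(family))),
    )
    for key in ("alpha", "B", "resample_unit", "regression_covariates", "write_surveys", "ci_level"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# stage helpers


def _child_seed(seed: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, k])


def _bootstrap_seed(seed: int) -> int:
    return int(_child_seed(seed, 3).generate_state(1)[0] % (2**31))


def quantity_name(q: tuple) -> str:
    if q[0] == "outcome":
        return f"{q[1]}:{q[2]}"
    return f"{q[1]}={q[2]}"


def quantity_indicator(q: tuple) -> Callable[[pd.DataFrame], np.ndarray]:
    if q[0] == "outcome":
        _, outcome, recency = q
        return lambda df: harmonize.recency_indicator(df, outcome, recency)
    _, cov, level = q
    return lambda df: (df[cov].astype(str) == level).to_numpy()


def estimates_table(
    surveys: list[SurveyDataset], family: list[tuple], level: float = 0.95
) -> pd.DataFrame:
    """Design-based estimate (percent scale) for every quantity x survey."""
    rows = []
    for ds in surveys:
        for q in family:
            est = estimation.estimate_prevalence(
                ds,
                quantity_indicator(q),
                outcome=q[1],
                recency=q[2] if q[0] == "outcome" else "",
                level=level,
            )
            rows.append(
                {
                    "quantity": quantity_name(q),
                    "survey": ds.label,
                    "pct": 100 * est.p_hat,
                    "se_pct": 100 * est.se,
                    "ci_low_pct": 100 * est.ci_low,
                    "ci_high_pct": 100 * est.ci_high,
                    "n_unweighted": est.n_unweighted,
                    "weighted_total": est.weighted_total,
                    "level": est.level,
                    "ci_method": est.ci_method,
                }
            )
    return pd.DataFrame(rows)


def differences_table(
    survey_a: SurveyDataset,
    survey_b: SurveyDataset,
    family: list[tuple],
    B: int,
    alpha: float,
    m: int,
    seed: int,
    resample_unit: str = "psu",
    estimates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Bootstrap-mean differences (survey B minus survey A), percent scale."""
    indicators = {quantity_name(q): quantity_indicator(q) for q in family}
    diffs, info = compare_mod.bootstrap_differences(
        survey_a,
        survey_b,
        indicators,
        B=B,
        seed=seed,
        resample_unit_a=resample_unit if survey_a.kind == PROBABILITY_CLUSTERED else "respondent",
        resample_unit_b="respondent" if survey_b.kind == OPTIN_PANEL else resample_unit,
    )
    rows = []
    for name in diffs.columns:
        de = compare_mod.summarize_difference(
            100 * diffs[name].to_numpy(),
            alpha=alpha,
            m=m,
            quantity=name,
            seed=seed,
            n_excluded=info["n_excluded"],
        )
        row = de.to_dict()
        if estimates is not None:
            for ds, tag in ((survey_a, "a"), (survey_b, "b")):
                sub = estimates[(estimates["quantity"] == name) & (estimates["survey"] == ds.label)]
                row[f"est_{tag}_pct"] = float(sub["pct"].iloc[0])
                row[f"est_{tag}_ci_low_pct"] = float(sub["ci_low_pct"].iloc[0])
                row[f"est_{tag}_ci_high_pct"] = float(sub["ci_high_pct"].iloc[0])
            row["plain_diff_pct"] = row["est_b_pct"] - row["est_a_pct"]
        rows.append(row)
    return pd.DataFrame(rows), info


def family_truth(
    population_h: pd.DataFrame, family: list[tuple]
) -> dict[str, float]:
    """Exhaustive population value (percent) of every family quantity."""
    out = {}
    for q in family:
        y = quantity_indicator(q)(population_h)
        out[quantity_name(q)] = 100.0 * float(np.mean(y))
    return out


def recovery_report(
    estimates: pd.DataFrame,
    differences: pd.DataFrame,
    truth_pct: dict[str, float],
    survey_a_label: str = "probability",
    truth_delta_pct: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-quantity truth vs estimates, with CI/cCI coverage flags.

    ``truth_delta_pct`` optionally supplies the true cross-survey difference
    per quantity (e.g. 0 for null designs); when absent the difference
    coverage column is left empty, since a selection-biased panel has no
    population-level difference truth.
    """
    rows = []
    for _, d in differences.iterrows():
        name = d["quantity"]
        t = truth_pct.get(name, np.nan)
        ea = estimates[(estimates["quantity"] == name) & (estimates["survey"] == survey_a_label)]
        row = {
            "quantity": name,
            "truth_pct": t,
            "est_a_pct": float(ea["pct"].iloc[0]),
            "bias_a_pct": float(ea["pct"].iloc[0]) - t,
            "ci_a_covers_truth": bool(
                float(ea["ci_low_pct"].iloc[0]) <= t <= float(ea["ci_high_pct"].iloc[0])
            ),
            "diff_point_pct": d["diff_point"],
        }
        if truth_delta_pct is not None and name in truth_delta_pct:
            delta = truth_delta_pct[name]
            row["truth_delta_pct"] = delta
            row["ci_covers_delta"] = bool(d["ci_low"] <= delta <= d["ci_high"])
            row["cci_covers_delta"] = bool(d["cci_low"] <= delta <= d["cci_high"])
        rows.append(row)
    return pd.DataFrame(rows)


def regression_tables(
    ds: SurveyDataset,
    outcome: tuple[str, str],
    covariates: list[str],
    references: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame, regression.LogisticModelResult]:
    y = harmonize.recency_indicator(ds.data, outcome[0], outcome[1]).astype(float)
    model = regression.fit_weighted_logit(ds, y, covariates, references)
    table = model.to_frame()
    table.insert(0, "survey", ds.label)
    table["vif"] = [model.vif.get(c, np.nan) for c in table["covariate"]]
    ames = regression.average_marginal_effects(model, ds, covariates)
    ame_df = pd.DataFrame([a.to_dict() for a in ames])
    ame_df.insert(0, "survey", ds.label)
    return table, ame_df, model


# ---------------------------------------------------------------------------
# the run


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full pipeline; returns a summary dict with artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **kv: Any) -> None:
        log_lines.append(json.dumps({"stage": stage, **_jsonable(kv)}, sort_keys=True))

    try:
        population, realized = synthetic_data.generate_population(
            config.truth, _child_seed(config.seed, 0)
        )
        log("generate_population", n=len(population), realized=realized)

        survey_a = synthetic_data.draw_probability_sample(
            population, config.design_probability, _child_seed(config.seed, 1)
        )
        survey_b = synthetic_data.draw_optin_sample(
            population, config.design_optin, _child_seed(config.seed, 2)
        )
        log("draw_samples", n_a=survey_a.n, n_b=survey_b.n,
            weighted_a=survey_a.weighted_total, weighted_b=survey_b.weighted_total)

        survey_a = harmonize.harmonize_dataset(survey_a)
        survey_b = harmonize.harmonize_dataset(survey_b)
        population_h = harmonize.harmonize_frame(population)
        truth_pct = family_truth(population_h, config.family)
        log("harmonize", n_a=survey_a.n, n_b=survey_b.n)

        if config.write_surveys:
            survey_a.write(out / "survey_probability")
            survey_b.write(out / "survey_panel")

        estimates = estimates_table([survey_a, survey_b], config.family, config.ci_level)
        estimates.to_csv(out / "estimates.csv", index=False)
        log("estimate", rows=len(estimates))

        boot_seed = _bootstrap_seed(config.seed)
        differences, boot_info = differences_table(
            survey_a,
            survey_b,
            config.family,
            B=config.B,
            alpha=config.alpha,
            m=config.m,
            seed=boot_seed,
            resample_unit=config.resample_unit,
            estimates=estimates,
        )
        differences.to_csv(out / "differences.csv", index=False)
        log("compare", **boot_info)

        reg_rows, ame_rows, models = [], [], {}
        for ds in (survey_a, survey_b):
            table, ame_df, model = regression_tables(
                ds, config.regression_outcome, config.regression_covariates, config.reference_levels
            )
            reg_rows.append(table)
            ame_rows.append(ame_df)
            models[ds.label] = model
            log("regress", survey=ds.label, converged=model.converged,
                iterations=model.iterations, vif_flagged=model.vif_flagged)
        pd.concat(reg_rows, ignore_index=True).to_csv(out / "regression.csv", index=False)
        pd.concat(ame_rows, ignore_index=True).to_csv(out / "ame.csv", index=False)

        recovery = recovery_report(estimates, differences, truth_pct, survey_a.label)
        recovery.to_csv(out / "recovery.csv", index=False)
        log("recover", rows=len(recovery))
    except Exception as err:
        # abort cleanly: remove partial CSV outputs, keep nothing half-written
        for p in out.glob("*.csv"):
            p.unlink()
        raise RuntimeError(f"pipeline aborted: {err}") from err

    import crossprev

    manifest = {
        "schema_version": 1,
        "package_version": crossprev.__version__,
        "seed": config.seed,
        "child_seed_scheme": "SeedSequence([seed, stage]); bootstrap replicate b of "
        "survey s uses SeedSequence([boot_seed, b, s])",
        "bootstrap_seed": _bootstrap_seed(config.seed),
        "B": config.B,
        "m": config.m,
        "alpha": config.alpha,
        "alpha_corrected": config.alpha / config.m,
        "resample_unit": {
            "probability": config.resample_unit,
            "panel": "respondent",
        },
        "difference_direction": f"{survey_b.label} minus {survey_a.label}",
        "quantile_rule": "inverse empirical CDF, linear interpolation",
        "ci_method": "logit-transformed design-based intervals",
        "reweight_per_replicate": False,
        "family": [list(q) for q in config.family],
        "family_note": "reconstructed comparison family; not a published list",
        "realized_truth": realized,
        "family_truth_pct": truth_pct,
        "regression": {
            "outcome": list(config.regression_outcome),
            "covariates": config.regression_covariates,
            "reference_levels": config.reference_levels,
            "ci_convention": "wald-normal",
        },
        "n_respondents": {"probability": survey_a.n, "panel": survey_b.n},
        "weighted_totals": {
            "probability": survey_a.weighted_total,
            "panel": survey_b.weighted_total,
        },
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "out_dir": str(out),
        "estimates": estimates,
        "differences": differences,
        "recovery": recovery,
        "models": models,
        "realized_truth": realized,
        "truth_pct": truth_pct,
        "manifest": manifest,
    }


def _versions() -> dict[str, str]:
    import scipy

    import crossprev

    return {
        "crossprev": crossprev.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def output_hashes(out_dir: str | Path) -> dict[str, str]:
    """SHA-256 of every CSV artifact in a run directory."""
    out = Path(out_dir)
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.glob("*.csv"))
    }
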