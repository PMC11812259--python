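"""Synthetic dual-survey generator with known population truth.

Builds a latent adult population with categorical covariates and two rare
latent outcomes (past-year heroin use and past-year illicitly manufactured
fentanyl use) realized from per-outcome logistic models, then draws from that
single population:

* a stratified two-stage probability sample (PSUs without replacement within
  strata, persons without replacement within PSUs) with logistic nonresponse
  and inverse-response-rate weight adjustment — the household-survey arm; and
* an opt-in panel in which each person joins independently with a
  covariate-dependent (optionally outcome-dependent) self-selection
  probability, weighted by raking to population margins — the online-panel
  arm.

Because the population is realized explicitly, every downstream estimator can
be checked against exhaustive population counts.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dataset import (
    OPTIN_PANEL,
    PROBABILITY_CLUSTERED,
    DesignError,
    SurveyDataset,
    SurveyDesignSpec,
)
from .harmonize import Recency

OUTCOMES = ("heroin", "imf")
RECENCY_LABELS = ("none", "months_2_12", "past_month")


class ParameterError(ValueError):
    """Generator parameters are inconsistent or non-finite."""


class RakingError(ValueError):
    """Iterative proportional fitting cannot reach the requested margins."""


@dataclass
class PopulationTruth:
    """Ground-truth parameters of the synthetic latent population.

    ``covariates`` maps covariate name -> {level: marginal probability}
    (marginals must sum to 1).  ``outcome_models`` maps outcome name
    ("heroin", "imf") -> {"intercept": float, "effects": {covariate:
    {level: log-odds}}}.  ``recency_split`` is the per-outcome probability
    that a past-year user is a past-month user (the remainder used 2-12
    months ago).  ``tilts`` optionally induces pairwise association between
    an arbitrary covariate level and a *binary* covariate: each entry is
    ``(given_cov, given_level, target_cov, target_level, log_odds)``.
    """

    pop_size: int
    covariates: dict[str, dict[str, float]]
    outcome_models: dict[str, dict]
    recency_split: dict[str, float]
    tilts: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pop_size < 1:
            raise ParameterError("pop_size must be >= 1")
        for cov, levels in self.covariates.items():
            probs = np.array(list(levels.values()), dtype=float)
            if np.any(probs < 0):
                raise ParameterError(f"covariate {cov!r}: negative marginal probability")
            if abs(probs.sum() - 1.0) > 1e-12:
                raise ParameterError(
                    f"covariate {cov!r}: marginals sum to {probs.sum()!r}, not 1"
                )
        for outcome in OUTCOMES:
            if outcome not in self.outcome_models:
                raise ParameterError(f"outcome model for {outcome!r} missing")
            model = self.outcome_models[outcome]
            coefs = [model["intercept"]] + [
                v for lv in model.get("effects", {}).values() for v in lv.values()
            ]
            if not np.all(np.isfinite(coefs)):
                raise ParameterError(f"outcome {outcome!r}: non-finite coefficient")
            for cov, lv in model.get("effects", {}).items():
                if cov not in self.covariates:
                    raise ParameterError(f"outcome {outcome!r} references unknown covariate {cov!r}")
                for level in lv:
                    if level not in self.covariates[cov]:
                        raise ParameterError(
                            f"outcome {outcome!r}: unknown level {level!r} of {cov!r}"
                        )
            split = self.recency_split.get(outcome)
            if split is None or not (0.0 <= split <= 1.0):
                raise ParameterError(f"recency_split[{outcome!r}] must be in [0, 1]")

    def active_covariates(self) -> list[str]:
        """Covariates entering at least one outcome model (order preserved)."""
        active: list[str] = []
        for outcome in OUTCOMES:
            for cov in self.outcome_models[outcome].get("effects", {}):
                if cov not in active:
                    active.append(cov)
        return active


# ---------------------------------------------------------------------------
# exact model-implied prevalence (enumeration over the covariate joint)


def model_implied_prevalence(truth: PopulationTruth) -> dict[str, dict[str, float]]:
    """Exact marginal prevalences implied by the outcome models.

    Enumerates the joint distribution of the covariates that carry nonzero
    coefficients (independence lets all other covariates integrate out) and
    averages the per-cell logistic probabilities.  Refuses to run when
    association tilts are set, because the joint is then no longer the
    product of the marginals; realized counts from a generated table are the
    truth source in that case.
    """
    if truth.tilts:
        raise ParameterError(
            "model_implied_prevalence requires independent covariates (no tilts)"
        )
    active = truth.active_covariates()
    level_lists = [list(truth.covariates[c].keys()) for c in active]
    prob_lists = [list(truth.covariates[c].values()) for c in active]

    s_h = truth.recency_split["heroin"]
    s_f = truth.recency_split["imf"]
    acc = {
        "heroin": {"past_year": 0.0, "past_month": 0.0},
        "imf": {"past_year": 0.0, "past_month": 0.0},
        "either": {"past_year": 0.0, "past_month": 0.0},
    }
    for combo in itertools.product(*[range(len(ll)) for ll in level_lists]):
        p_cell = 1.0
        for probs, idx in zip(prob_lists, combo):
            p_cell *= probs[idx]
        if p_cell == 0.0:
            continue
        etas = {}
        for outcome in OUTCOMES:
            model = truth.outcome_models[outcome]
            eta = model["intercept"]
            effects = model.get("effects", {})
            for cov, levels, idx in zip(active, level_lists, combo):
                eta += effects.get(cov, {}).get(levels[idx], 0.0)
            etas[outcome] = eta
        p_h = float(expit(etas["heroin"]))
        p_f = float(expit(etas["imf"]))
        acc["heroin"]["past_year"] += p_cell * p_h
        acc["imf"]["past_year"] += p_cell * p_f
        acc["either"]["past_year"] += p_cell * (p_h + p_f - p_h * p_f)
        acc["heroin"]["past_month"] += p_cell * p_h * s_h
        acc["imf"]["past_month"] += p_cell * p_f * s_f
        acc["either"]["past_month"] += p_cell * (1.0 - (1.0 - p_h * s_h) * (1.0 - p_f * s_f))
    for out in acc.values():
        out["months_2_12"] = out["past_year"] - out["past_month"]
    return acc


def calibrate_intercept(
    truth: PopulationTruth,
    outcome: str,
    target: float,
    quantity: tuple[str, str] | None = None,
) -> PopulationTruth:
    """Return a copy of ``truth`` with ``outcome``'s intercept set so the
    model-implied prevalence of ``quantity`` (default: that outcome's
    past-year use) equals ``target``."""
    if quantity is None:
        quantity = (outcome, "past_year")
    q_out, q_rec = quantity

    def objective(b0: float) -> float:
        models = copy.deepcopy(truth.outcome_models)
        models[outcome]["intercept"] = b0
        trial = replace(truth, outcome_models=models)
        return model_implied_prevalence(trial)[q_out][q_rec] - target

    b0 = brentq(objective, -30.0, 10.0, xtol=1e-12)
    models = copy.deepcopy(truth.outcome_models)
    models[outcome]["intercept"] = float(b0)
    return replace(truth, outcome_models=models)


# ---------------------------------------------------------------------------
# population generation


def _linear_predictor(df: pd.DataFrame, model: dict) -> np.ndarray:
    eta = np.full(len(df), float(model["intercept"]))
    for cov, levels in model.get("effects", {}).items():
        eta += df[cov].map(levels).fillna(0.0).astype(float).to_numpy()
    return eta


def generate_population(
    truth: PopulationTruth, seed: int
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Realize the latent population table and its exact true prevalences.

    Returns ``(table, realized)`` where ``realized[outcome][recency]`` is the
    exhaustive population proportion recomputed from the table.  Identical
    ``(truth, seed)`` give a byte-identical table.
    """
    rng = np.random.default_rng(seed)
    n = truth.pop_size
    cols: dict[str, pd.Categorical] = {}
    for cov, levels in truth.covariates.items():
        labels = list(levels.keys())
        probs = np.array(list(levels.values()), dtype=float)
        probs = probs / probs.sum()  # guard rounding at the 1e-12 scale
        codes = rng.choice(len(labels), size=n, p=probs)
        cols[cov] = pd.Categorical.from_codes(codes, categories=labels)
    df = pd.DataFrame(cols)

    for given_cov, given_level, target_cov, target_level, log_odds in truth.tilts:
        levels = list(truth.covariates[target_cov].keys())
        if len(levels) != 2:
            raise ParameterError(
                f"tilt target {target_cov!r} must be binary (has {len(levels)} levels)"
            )
        base_p = truth.covariates[target_cov][target_level]
        mask = (df[given_cov] == given_level).to_numpy()
        tilted_p = float(expit(np.log(base_p / (1.0 - base_p)) + log_odds))
        other = levels[0] if levels[1] == target_level else levels[1]
        redraw = rng.random(int(mask.sum())) < tilted_p
        new_vals = np.where(redraw, target_level, other)
        col = df[target_cov].astype(object).to_numpy()
        col[mask] = new_vals
        df[target_cov] = pd.Categorical(col, categories=levels)

    for outcome in OUTCOMES:
        eta = _linear_predictor(df, truth.outcome_models[outcome])
        if not np.all(np.isfinite(eta)):
            raise ParameterError(f"outcome {outcome!r}: non-finite linear predictor")
        p = expit(eta)
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ParameterError(f"outcome {outcome!r}: probability outside [0, 1]")
        past_year = rng.random(n) < p
        past_month = past_year & (rng.random(n) < truth.recency_split[outcome])
        rec = np.where(past_month, Recency.PAST_MONTH, np.where(past_year, Recency.MONTHS_2_12, Recency.NONE))
        df[f"{outcome}_recency"] = pd.Categorical.from_codes(rec, categories=list(RECENCY_LABELS))

    h = df["heroin_recency"].cat.codes.to_numpy()
    f = df["imf_recency"].cat.codes.to_numpy()
    df["either_recency"] = pd.Categorical.from_codes(
        np.maximum(h, f), categories=list(RECENCY_LABELS)
    )
    df.insert(0, "person_id", np.arange(n))
    return df, realized_prevalence(df)


def realized_prevalence(table: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Exhaustive per-outcome prevalence counts over a population table."""
    n = len(table)
    out: dict[str, dict[str, float]] = {}
    for outcome in ("heroin", "imf", "either"):
        col = table[f"{outcome}_recency"]
        pm = float((col == "past_month").sum()) / n
        m212 = float((col == "months_2_12").sum()) / n
        py = float((col != "none").sum()) / n
        out[outcome] = {"past_year": py, "past_month": pm, "months_2_12": m212}
    return out


def population_margins(
    population: pd.DataFrame, covariates: list[str]
) -> dict[str, dict[str, float]]:
    """Population category counts used as raking targets."""
    return {
        cov: {str(k): float(v) for k, v in population[cov].value_counts().items()}
        for cov in covariates
    }


# ---------------------------------------------------------------------------
# probability-sample arm


def _propensity(df: pd.DataFrame, model: dict) -> np.ndarray:
    eta = np.full(len(df), float(model.get("_intercept", 0.0)))
    for cov, levels in model.items():
        if cov == "_intercept":
            continue
        eta += df[cov].map(levels).fillna(0.0).astype(float).to_numpy()
    return expit(eta)


def _apply_past_month_misclass(df: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    """Flip observed past-month responses to 2-12 months with probability ``rate``.

    Models the "4 weeks" vs "past 30 days" wording difference; off by default.
    """
    if rate <= 0:
        return df
    df = df.copy()
    for outcome in OUTCOMES:
        col = df[f"{outcome}_recency"].astype(object).to_numpy()
        pm = col == "past_month"
        flip = pm & (rng.random(len(df)) < rate)
        col[flip] = "months_2_12"
        df[f"{outcome}_recency"] = pd.Categorical(col, categories=list(RECENCY_LABELS))
    h = pd.Categorical(df["heroin_recency"], categories=list(RECENCY_LABELS)).codes
    f = pd.Categorical(df["imf_recency"], categories=list(RECENCY_LABELS)).codes
    df["either_recency"] = pd.Categorical.from_codes(
        np.maximum(h, f), categories=list(RECENCY_LABELS)
    )
    return df


def draw_probability_sample(
    population: pd.DataFrame,
    design: SurveyDesignSpec,
    seed: int,
    past_month_misclass: float = 0.0,
) -> SurveyDataset:
    """Stratified two-stage probability sample with nonresponse adjustment.

    Persons are partitioned into ``n_strata x psus_per_stratum`` cells (a
    random partition by default); ``sample_psus_per_stratum`` PSUs are drawn
    without replacement per stratum and ``respondents_per_psu`` persons
    without replacement per sampled PSU.  Base weight = inverse inclusion
    probability.  Nonresponse thins respondents by a logistic propensity;
    weights of respondents are multiplied by the inverse response rate within
    adjustment cells formed by crossing the propensity model's covariates,
    which redistributes the nonrespondents' weight mass exactly.
    """
    if design.kind != PROBABILITY_CLUSTERED:
        raise DesignError("draw_probability_sample needs a probability_clustered design")
    rng = np.random.default_rng(seed)
    n_pop = len(population)
    n_cells = design.n_strata * design.psus_per_stratum
    if n_pop < n_cells:
        raise DesignError("population smaller than the stratum x PSU grid")

    if design.psu_assignment == "random":
        order = rng.permutation(n_pop)
    elif design.psu_assignment == "sequential":
        order = np.arange(n_pop)
    else:
        raise DesignError(f"unknown psu_assignment {design.psu_assignment!r}")
    strata_blocks = np.array_split(order, design.n_strata)

    taken_rows: list[np.ndarray] = []
    strat_labels: list[np.ndarray] = []
    psu_labels: list[np.ndarray] = []
    base_weights: list[np.ndarray] = []
    m = design.sample_psus_per_stratum
    for h, block in enumerate(strata_blocks):
        psu_blocks = np.array_split(block, design.psus_per_stratum)
        chosen = rng.choice(design.psus_per_stratum, size=m, replace=False)
        for k in chosen:
            members = psu_blocks[k]
            r = min(design.respondents_per_psu, len(members))
            if r == 0:
                raise DesignError(f"empty PSU {k} in stratum {h}")
            pick = rng.choice(len(members), size=r, replace=False)
            rows = members[pick]
            taken_rows.append(rows)
            strat_labels.append(np.full(r, f"S{h:03d}"))
            psu_labels.append(np.full(r, f"S{h:03d}-P{k:03d}"))
            w = (design.psus_per_stratum / m) * (len(members) / r)
            base_weights.append(np.full(r, w))

    rows = np.concatenate(taken_rows)
    sample = population.iloc[rows].reset_index(drop=True)
    sample["stratum"] = np.concatenate(strat_labels)
    sample["psu"] = np.concatenate(psu_labels)
    sample["weight"] = np.concatenate(base_weights)

    meta: dict = {"seed": seed, "design": design.to_dict(), "n_sampled": len(sample)}
    if design.nonresponse_model:
        p_resp = _propensity(sample, design.nonresponse_model)
        respond = rng.random(len(sample)) < p_resp
        cell_covs = [c for c in design.nonresponse_model if c != "_intercept"]
        if cell_covs:
            cell = sample[cell_covs].astype(str).agg("|".join, axis=1)
        else:
            cell = pd.Series("all", index=sample.index)
        sampled_mass = sample.groupby(cell, observed=True)["weight"].sum()
        resp_mass = sample.loc[respond].groupby(cell[respond], observed=True)["weight"].sum()
        adj = (sampled_mass / resp_mass.reindex(sampled_mass.index)).fillna(0.0)
        covered = float((sampled_mass * (adj > 0)).sum())
        respondents = sample.loc[respond].copy()
        respondents["weight"] = respondents["weight"].to_numpy() * adj.loc[
            cell[respond]
        ].to_numpy()
        # cells that lost every respondent: spread their mass over everyone
        lost = float(sampled_mass.sum()) - covered
        if lost > 0:
            respondents["weight"] *= sampled_mass.sum() / covered
        dropped_psus = sorted(set(sample["psu"]) - set(respondents["psu"]))
        if dropped_psus:
            meta["dropped_psus"] = dropped_psus
        meta["response_rate"] = float(respond.mean())
        sample = respondents.reset_index(drop=True)
        if len(sample) == 0:
            raise DesignError("no respondents after nonresponse thinning")

    sample = _apply_past_month_misclass(sample, past_month_misclass, rng)
    return SurveyDataset(
        data=sample,
        kind=PROBABILITY_CLUSTERED,
        weight_col="weight",
        stratum_col="stratum",
        psu_col="psu",
        label=design.label,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# opt-in panel arm


def draw_optin_sample(
    population: pd.DataFrame,
    design: SurveyDesignSpec,
    seed: int,
    raking_tol: float = 1e-8,
    raking_max_iter: int = 100,
    past_month_misclass: float = 0.0,
) -> SurveyDataset:
    """Opt-in panel: independent self-selection, then raking to population margins.

    Each person joins with probability ``expit(selection_model)``; joiners get
    uniform initial weights ``pop_size / n`` and, when ``raking_margins`` is
    nonempty, weights calibrated by iterative proportional fitting to the
    population category counts.  Respondents are split into two pooled waves.
    """
    if design.kind != OPTIN_PANEL:
        raise DesignError("draw_optin_sample needs an optin_panel design")
    rng = np.random.default_rng(seed)
    p_join = _propensity(population, design.selection_model)
    join = rng.random(len(population)) < p_join
    n = int(join.sum())
    if n == 0:
        raise DesignError("opt-in selection produced an empty sample")
    sample = population.loc[join].reset_index(drop=True)
    sample["wave"] = rng.integers(1, 3, size=n)
    sample["weight"] = len(population) / n
    sample = _apply_past_month_misclass(sample, past_month_misclass, rng)

    ds = SurveyDataset(
        data=sample,
        kind=OPTIN_PANEL,
        weight_col="weight",
        stratum_col=None,
        psu_col=None,
        label=design.label,
        meta={"seed": seed, "design": design.to_dict(), "n_sampled": n},
    )
    if design.raking_margins:
        margins = population_margins(population, design.raking_margins)
        ds = rake_weights(ds, margins, tol=raking_tol, max_iter=raking_max_iter)
    return ds


def rake_weights(
    sample: SurveyDataset,
    margins: dict[str, dict[str, float]],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SurveyDataset:
    """Calibrate weights by iterative proportional fitting (raking).

    ``margins`` maps covariate -> {level: population total}.  Cycles over the
    margins multiplying weights by (target total / current weighted total)
    per category until every weighted category share is within ``tol`` of its
    target share, and the weight sum matches the population total.  Margins
    already satisfied are returned unchanged (zero adjustment cycles).
    """
    if tol <= 0:
        raise ParameterError("raking tol must be > 0")
    df = sample.data
    w = df[sample.weight_col].to_numpy(dtype=float).copy()

    totals = {m: float(sum(lv.values())) for m, lv in margins.items()}
    target_total = next(iter(totals.values()))
    for m, t in totals.items():
        if abs(t - target_total) > 1e-6 * max(1.0, target_total):
            raise RakingError(f"margin {m!r} total {t} disagrees with {target_total}")

    codes: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    for margin, level_totals in margins.items():
        levels = list(level_totals.keys())
        observed = df[margin].astype(str)
        unknown = set(observed.unique()) - set(levels)
        if unknown:
            raise RakingError(f"margin {margin!r}: sample levels {sorted(unknown)} have no target")
        code = pd.Categorical(observed, categories=levels).codes
        tgt = np.array([level_totals[lv] for lv in levels], dtype=float)
        present = np.bincount(code, minlength=len(levels)) > 0
        missing = [lv for lv, ok, t in zip(levels, present, tgt) if not ok and t > 0]
        if missing:
            raise RakingError(
                f"margin {margin!r}: categories {missing} absent from the sample; "
                "raking cannot converge"
            )
        codes[margin] = code
        targets[margin] = tgt

    def max_deviation(w: np.ndarray) -> float:
        dev = abs(w.sum() - target_total) / target_total
        for margin in margins:
            cur = np.bincount(codes[margin], weights=w, minlength=len(targets[margin]))
            dev = max(dev, float(np.max(np.abs(cur / w.sum() - targets[margin] / target_total))))
        return dev

    iterations = 0
    for it in range(max_iter):
        if max_deviation(w) <= tol:
            break
        for margin in margins:
            cur = np.bincount(codes[margin], weights=w, minlength=len(targets[margin]))
            factor = np.where(cur > 0, targets[margin] / np.where(cur > 0, cur, 1.0), 1.0)
            w = w * factor[codes[margin]]
        iterations = it + 1
    final_dev = max_deviation(w)
    if final_dev > tol:
        raise RakingError(
            f"raking did not converge in {max_iter} iterations (max deviation {final_dev:.3g})"
        )
    out = df.copy()
    out[sample.weight_col] = w
    return sample.with_data(
        out, raking={"iterations": iterations, "max_deviation": final_dev, "tol": tol}
    )
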