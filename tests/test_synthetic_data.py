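"""Generator correctness: realized truth, sampling weights, raking, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from crossprev.dataset import (
    OPTIN_PANEL,
    PROBABILITY_CLUSTERED,
    DesignError,
    SurveyDesignSpec,
)
from crossprev.synthetic_data import (
    ParameterError,
    PopulationTruth,
    RakingError,
    calibrate_intercept,
    draw_optin_sample,
    draw_probability_sample,
    generate_population,
    model_implied_prevalence,
    rake_weights,
)
from tests.conftest import make_optin_dataset


def tiny_truth(pop_size=10_000, heroin_intercept=-3.0, imf_intercept=-3.5, effects=True):
    eff_h = {"employment": {"yes": -0.8}, "stimulant": {"yes": 2.0}} if effects else {}
    eff_f = {"stimulant": {"yes": 2.5}} if effects else {}
    return PopulationTruth(
        pop_size=pop_size,
        covariates={
            "employment": {"yes": 0.6, "no": 0.4},
            "stimulant": {"yes": 0.05, "no": 0.95},
            "education": {"college": 0.35, "no college": 0.65},
        },
        outcome_models={
            "heroin": {"intercept": heroin_intercept, "effects": eff_h},
            "imf": {"intercept": imf_intercept, "effects": eff_f},
        },
        recency_split={"heroin": 0.6, "imf": 0.4},
    )


class TestTruthValidation:
    def test_marginals_must_sum_to_one(self):
        with pytest.raises(ParameterError, match="marginals"):
            PopulationTruth(
                pop_size=10,
                covariates={"a": {"x": 0.6, "y": 0.5}},
                outcome_models={
                    "heroin": {"intercept": 0.0},
                    "imf": {"intercept": 0.0},
                },
                recency_split={"heroin": 0.5, "imf": 0.5},
            )

    def test_nonfinite_coefficient_rejected(self):
        with pytest.raises(ParameterError, match="non-finite"):
            tiny = tiny_truth()
            PopulationTruth(
                pop_size=10,
                covariates=tiny.covariates,
                outcome_models={
                    "heroin": {"intercept": float("nan")},
                    "imf": {"intercept": 0.0},
                },
                recency_split={"heroin": 0.5, "imf": 0.5},
            )

    def test_recency_split_bounds(self):
        with pytest.raises(ParameterError, match="recency_split"):
            tiny = tiny_truth()
            PopulationTruth(
                pop_size=10,
                covariates=tiny.covariates,
                outcome_models=tiny.outcome_models,
                recency_split={"heroin": 1.5, "imf": 0.5},
            )


class TestGeneratePopulation:
    def test_identical_seed_identical_table(self):
        truth = tiny_truth(pop_size=2000)
        df1, r1 = generate_population(truth, seed=9)
        df2, r2 = generate_population(truth, seed=9)
        pd.testing.assert_frame_equal(df1, df2)
        assert r1 == r2

    def test_effectively_impossible_outcome_never_occurs(self):
        truth = tiny_truth(pop_size=10_000, heroin_intercept=-50.0, imf_intercept=-50.0,
                           effects=False)
        df, realized = generate_population(truth, seed=0)
        assert realized["heroin"]["past_year"] == 0.0
        assert (df["either_recency"] == "none").all()

    def test_even_odds_intercept_gives_half(self):
        truth = tiny_truth(pop_size=200_000, heroin_intercept=0.0, imf_intercept=-50.0,
                           effects=False)
        _, realized = generate_population(truth, seed=1)
        mc_se = np.sqrt(0.25 / 200_000)
        assert abs(realized["heroin"]["past_year"] - 0.5) < 3 * mc_se

    def test_realized_matches_bruteforce_model_implied(self):
        """Calibrate either-use to 1.05% and check the realized prevalence at
        pop 500k against a brute-force expectation over all covariate cells,
        enumerated independently of the package."""
        truth = calibrate_intercept(
            tiny_truth(pop_size=500_000, heroin_intercept=-6.0, imf_intercept=-6.0),
            "imf",
            0.0105,
            quantity=("either", "past_year"),
        )
        # independent brute-force enumeration over the full covariate joint
        covs = list(truth.covariates)
        expected = 0.0
        for combo in itertools.product(*[truth.covariates[c].items() for c in covs]):
            p_cell = 1.0
            assign = {}
            for c, (level, prob) in zip(covs, combo):
                p_cell *= prob
                assign[c] = level
            etas = {}
            for outcome in ("heroin", "imf"):
                model = truth.outcome_models[outcome]
                eta = model["intercept"]
                for c, lv in model.get("effects", {}).items():
                    eta += lv.get(assign[c], 0.0)
                etas[outcome] = eta
            ph, pf = expit(etas["heroin"]), expit(etas["imf"])
            expected += p_cell * (ph + pf - ph * pf)
        assert expected == pytest.approx(0.0105, abs=1e-9)  # calibration hit its target
        assert model_implied_prevalence(truth)["either"]["past_year"] == pytest.approx(
            expected, abs=1e-12
        )
        _, realized = generate_population(truth, seed=4)
        mc_se = np.sqrt(expected * (1 - expected) / truth.pop_size)
        assert abs(realized["either"]["past_year"] - expected) < 3 * mc_se

    def test_realized_recomputable_from_table(self):
        truth = tiny_truth(pop_size=5000)
        df, realized = generate_population(truth, seed=2)
        for outcome in ("heroin", "imf", "either"):
            col = df[f"{outcome}_recency"]
            assert realized[outcome]["past_month"] == (col == "past_month").mean()
            assert realized[outcome]["past_year"] == (col != "none").mean()
        e = realized["either"]["past_year"]
        assert e >= max(realized["heroin"]["past_year"], realized["imf"]["past_year"])
        assert e <= realized["heroin"]["past_year"] + realized["imf"]["past_year"]


class TestProbabilitySample:
    def test_self_weighting_equal_probability_design(self):
        """Equal-probability design, no nonresponse: all weights pop/n."""
        population = pd.DataFrame({"x": np.arange(800)})
        design = SurveyDesignSpec(
            kind=PROBABILITY_CLUSTERED,
            n_strata=2,
            psus_per_stratum=4,
            sample_psus_per_stratum=2,
            respondents_per_psu=50,
        )
        ds = draw_probability_sample(population, design, seed=3)
        # PSU size 100, half of PSUs sampled, half of each PSU sampled
        assert np.allclose(ds.weights, 800 / ds.n)
        assert ds.n == 2 * 2 * 50

    def test_sum_of_weights_near_population(self):
        truth = tiny_truth(pop_size=20_000)
        population, _ = generate_population(truth, seed=0)
        design = SurveyDesignSpec(
            kind=PROBABILITY_CLUSTERED,
            n_strata=4,
            psus_per_stratum=5,
            sample_psus_per_stratum=2,
            respondents_per_psu=100,
            nonresponse_model={"_intercept": 1.0, "employment": {"yes": -0.5}},
        )
        ds = draw_probability_sample(population, design, seed=1)
        assert abs(ds.weighted_total - 20_000) / 20_000 < 0.05

    def test_nonresponse_adjustment_matches_hand_computed_rates(self):
        """100-person toy population: final weight = base weight x inverse
        within-class response rate, computed by hand from the drawn sample."""
        rng = np.random.default_rng(0)
        population = pd.DataFrame(
            {"employment": np.where(rng.random(100) < 0.5, "yes", "no")}
        )
        design = SurveyDesignSpec(
            kind=PROBABILITY_CLUSTERED,
            n_strata=1,
            psus_per_stratum=2,
            sample_psus_per_stratum=2,
            respondents_per_psu=50,
            nonresponse_model={"_intercept": 1.2, "employment": {"yes": -1.5}},
        )
        ds = draw_probability_sample(population, design, seed=8)
        # reconstruct the pre-nonresponse sample: census of both PSUs, weight 1
        # response classes are employment levels; hand-compute inverse rates
        df = ds.data
        n_sampled = {"yes": (population["employment"] == "yes").sum(),
                     "no": (population["employment"] == "no").sum()}
        for level in ("yes", "no"):
            respondents = df[df["employment"] == level]
            expected_w = n_sampled[level] / len(respondents)
            assert np.allclose(respondents["weight"], expected_w)
        # employed persons respond less often -> larger adjusted weights
        assert df[df.employment == "yes"]["weight"].mean() > df[
            df.employment == "no"
        ]["weight"].mean()
        assert ds.weighted_total == pytest.approx(100.0, abs=1e-9)

    def test_too_few_psus_is_design_error(self):
        with pytest.raises(DesignError):
            SurveyDesignSpec(
                kind=PROBABILITY_CLUSTERED,
                n_strata=2,
                psus_per_stratum=1,
                sample_psus_per_stratum=2,
            )

    def test_draw_determinism(self):
        truth = tiny_truth(pop_size=3000)
        population, _ = generate_population(truth, seed=0)
        design = SurveyDesignSpec(
            kind=PROBABILITY_CLUSTERED,
            n_strata=2,
            psus_per_stratum=4,
            sample_psus_per_stratum=2,
            respondents_per_psu=40,
        )
        a = draw_probability_sample(population, design, seed=5)
        b = draw_probability_sample(population, design, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestOptinSample:
    def test_intercept_only_selection_with_matching_margins(self):
        """Simple random self-selection; raked weights stay near pop/n and
        match every margin within tolerance."""
        truth = tiny_truth(pop_size=30_000)
        population, _ = generate_population(truth, seed=0)
        design = SurveyDesignSpec(
            kind=OPTIN_PANEL,
            selection_model={"_intercept": -2.0},
            raking_margins=["employment", "education"],
        )
        ds = draw_optin_sample(population, design, seed=1, raking_tol=1e-9)
        for cov in ("employment", "education"):
            pop_share = population[cov].value_counts(normalize=True)
            got = ds.data.groupby(cov, observed=True)["weight"].sum() / ds.weighted_total
            for level in pop_share.index:
                assert got[level] == pytest.approx(pop_share[level], abs=1e-9)
        assert ds.weighted_total == pytest.approx(30_000, rel=1e-9)

    def test_selection_skew_corrected_by_raking(self):
        """Selection favoring college graduates: unweighted share exceeds the
        population share, raked weighted share matches it."""
        truth = tiny_truth(pop_size=30_000)
        population, _ = generate_population(truth, seed=0)
        design = SurveyDesignSpec(
            kind=OPTIN_PANEL,
            selection_model={"_intercept": -2.2, "education": {"college": 1.0}},
            raking_margins=["education"],
        )
        ds = draw_optin_sample(population, design, seed=2)
        pop_share = (population["education"] == "college").mean()
        unweighted = (ds.data["education"] == "college").mean()
        weighted = (
            ds.data.loc[ds.data["education"] == "college", "weight"].sum()
            / ds.weighted_total
        )
        assert unweighted > pop_share + 0.05
        assert weighted == pytest.approx(pop_share, abs=1e-6)

    def test_empty_selection_is_error(self):
        truth = tiny_truth(pop_size=500)
        population, _ = generate_population(truth, seed=0)
        design = SurveyDesignSpec(kind=OPTIN_PANEL, selection_model={"_intercept": -30.0})
        with pytest.raises(DesignError, match="empty"):
            draw_optin_sample(population, design, seed=0)


class TestRaking:
    def test_fixed_point_returns_weights_unchanged(self):
        ds = make_optin_dataset(
            y=[0, 1, 0, 1], w=[1.0, 1.0, 1.0, 1.0],
            extra={"g": ["a", "a", "b", "b"]},
        )
        out = rake_weights(ds, {"g": {"a": 2.0, "b": 2.0}}, tol=1e-10)
        np.testing.assert_array_equal(out.weights, ds.weights)
        assert out.meta["raking"]["iterations"] == 0

    def test_single_binary_margin_closed_form(self):
        """25/75 split with unit weights raked to 50/50: factors 2 and 2/3."""
        ds = make_optin_dataset(
            y=[0] * 4, w=[1.0] * 4, extra={"g": ["a", "b", "b", "b"]}
        )
        out = rake_weights(ds, {"g": {"a": 2.0, "b": 2.0}}, tol=1e-12)
        np.testing.assert_allclose(
            np.sort(out.weights), [2 / 3, 2 / 3, 2 / 3, 2.0], atol=1e-12
        )

    def test_two_margins_match_hand_executed_ipf(self):
        """8-person sample, 2 binary margins: compare against an independent
        iterative-proportional-fitting loop written out here."""
        g1 = ["a", "a", "a", "a", "b", "b", "b", "b"]
        g2 = ["x", "x", "y", "y", "x", "y", "y", "y"]
        w0 = np.array([1.0, 2.0, 1.0, 1.0, 1.5, 1.0, 0.5, 1.0])
        targets = {"g1": {"a": 6.0, "b": 4.0}, "g2": {"x": 5.0, "y": 5.0}}
        # independent IPF
        w = w0.copy()
        for _ in range(200):
            for margin, labels in (("g1", g1), ("g2", g2)):
                for level, tgt in targets[margin].items():
                    mask = np.array(labels) == level
                    w[mask] *= tgt / w[mask].sum()
        ds = make_optin_dataset(y=[0] * 8, w=w0, extra={"g1": g1, "g2": g2})
        out = rake_weights(ds, targets, tol=1e-12, max_iter=300)
        np.testing.assert_allclose(out.weights, w, atol=1e-9)

    def test_absent_margin_category_is_error(self):
        ds = make_optin_dataset(y=[0, 1], w=[1.0, 1.0], extra={"g": ["a", "a"]})
        with pytest.raises(RakingError, match="'b'"):
            rake_weights(ds, {"g": {"a": 1.0, "b": 1.0}})


def test_probability_estimator_unbiased_over_replicate_draws():
    """Parameter recovery: across 200 replicate draws the weighted either-use
    prevalence is unbiased for the realized population value."""
    from crossprev.estimation import weighted_proportion

    truth = tiny_truth(pop_size=6000, heroin_intercept=-2.2, imf_intercept=-2.6)
    population, realized = generate_population(truth, seed=0)
    p_true = realized["either"]["past_year"]
    design = SurveyDesignSpec(
        kind=PROBABILITY_CLUSTERED,
        n_strata=3,
        psus_per_stratum=5,
        sample_psus_per_stratum=2,
        respondents_per_psu=60,
        nonresponse_model={"_intercept": 1.3, "employment": {"yes": -0.4}},
    )
    estimates = []
    for r in range(200):
        ds = draw_probability_sample(population, design, seed=r)
        y = (ds.data["either_recency"] != "none").to_numpy()
        p, _, _ = weighted_proportion(y, ds.weights)
        estimates.append(p)
    estimates = np.array(estimates)
    mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - p_true) < 3 * mc_se
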