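import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crossprev import pipeline, synthetic_data
from crossprev.dataset import (
    OPTIN_PANEL,
    PROBABILITY_CLUSTERED,
    SurveyDataset,
    SurveyDesignSpec,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


def make_optin_dataset(y, w, label="toy", extra=None):
    """Small opt-in dataset from raw arrays (each respondent its own unit)."""
    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "weight": np.asarray(w, dtype=float)})
    for k, v in (extra or {}).items():
        df[k] = v
    return SurveyDataset(data=df, kind=OPTIN_PANEL, weight_col="weight", label=label)


def make_clustered_dataset(strata, psus, y, w, label="toy"):
    df = pd.DataFrame(
        {
            "stratum": list(strata),
            "psu": list(psus),
            "y": np.asarray(y, dtype=float),
            "weight": np.asarray(w, dtype=float),
        }
    )
    return SurveyDataset(
        data=df,
        kind=PROBABILITY_CLUSTERED,
        weight_col="weight",
        stratum_col="stratum",
        psu_col="psu",
        label=label,
    )


@pytest.fixture
def toy_clustered():
    """2 strata x 3 PSUs, 2 respondents each: small enough to verify by hand."""
    strata = ["A"] * 6 + ["B"] * 6
    psus = ["A1", "A1", "A2", "A2", "A3", "A3", "B1", "B1", "B2", "B2", "B3", "B3"]
    y = [1, 0, 1, 1, 0, 0, 1, 0, 0, 0, 1, 1]
    w = [1.0, 2.0, 1.5, 1.0, 2.0, 1.0, 1.0, 1.0, 3.0, 1.0, 1.0, 2.0]
    return make_clustered_dataset(strata, psus, y, w)


def moderate_truth(pop_size=40_000):
    """Small-population truth with non-rare outcomes for smoke/determinism runs."""
    truth = pipeline.default_truth(pop_size=pop_size, calibrate=False)
    models = {k: dict(v) for k, v in truth.outcome_models.items()}
    models["heroin"] = {**models["heroin"], "intercept": -3.6}
    models["imf"] = {**models["imf"], "intercept": -3.9}
    import dataclasses

    return dataclasses.replace(truth, outcome_models=models)


def small_config(seed=0, B=100):
    """Desk-scale end-to-end configuration exercising every stage."""
    family = [("outcome", o, r) for o, r in pipeline.OUTCOME_CELLS]
    family += [
        ("share", "sex", "female"),
        ("share", "education", "college graduate"),
        ("share", "race4", "another non-Hispanic race"),
    ]
    return pipeline.RunConfig(
        seed=seed,
        truth=moderate_truth(),
        design_probability=pipeline.default_probability_design(
            n_strata=6, psus_per_stratum=8, sample_psus_per_stratum=4, respondents_per_psu=100
        ),
        design_optin=pipeline.default_optin_design(selection_intercept=-2.2),
        family=family,
        m=len(family),
        B=B,
        regression_covariates=["sex", "cigarette_use", "stimulant_py", "benzo_py", "employment"],
        write_surveys=False,
    )
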