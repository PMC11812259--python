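"""Variable construction shared by both surveys.

Turns raw survey responses into the harmonized analytic dictionary:
a three-level recency of use (none < 2-12 months < past month) for heroin
and illicitly manufactured fentanyl (IMF), a derived "either heroin or IMF"
recency, the NIAAA heavy-alcohol classification, the four-level collapsed
race/ethnicity grouping used for modeling, and the rule that blank
cigarette-use responses count as "not at all".
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd

from .dataset import SurveyDataset


class Recency(IntEnum):
    """Most-recent-use category, totally ordered none < months_2_12 < past_month."""

    NONE = 0
    MONTHS_2_12 = 1
    PAST_MONTH = 2

    @property
    def label(self) -> str:
        return _RECENCY_LABELS[self]


_RECENCY_LABELS = {
    Recency.NONE: "none",
    Recency.MONTHS_2_12: "months_2_12",
    Recency.PAST_MONTH: "past_month",
}
RECENCY_FROM_LABEL = {v: k for k, v in _RECENCY_LABELS.items()}

# modeling vocabulary for race/ethnicity: sparse categories are collapsed
# into a single "another non-Hispanic race" group
RACE_COLLAPSE_MAP = {
    "non-Hispanic White": "non-Hispanic White",
    "non-Hispanic Black": "non-Hispanic Black",
    "Hispanic": "Hispanic",
    "Native American": "another non-Hispanic race",
    "Native Hawaiian": "another non-Hispanic race",
    "Asian": "another non-Hispanic race",
    "Multiple races": "another non-Hispanic race",
    "Other": "another non-Hispanic race",
}

CIGARETTE_LEVELS = ("every day", "some days", "not at all")

# NIAAA heavy-drinking thresholds, drinks per week
HEAVY_ALCOHOL_THRESHOLD = {"male": 15.0, "female": 8.0}


class HarmonizationError(ValueError):
    """A raw response violates the harmonized dictionary's consistency rules."""


def classify_recency(
    past_year_use: bool, past_month_use: bool, respondent_id: object = None
) -> Recency:
    """Map the two recency booleans to the three-level recency category.

    ``past_month_use`` implies ``past_year_use``; the reverse combination is a
    data-consistency error (a respondent cannot have used in the past month
    without using in the past year).
    """
    if past_month_use and not past_year_use:
        who = "" if respondent_id is None else f" (respondent {respondent_id!r})"
        raise HarmonizationError(
            f"past-month use reported without past-year use{who}"
        )
    if past_month_use:
        return Recency.PAST_MONTH
    if past_year_use:
        return Recency.MONTHS_2_12
    return Recency.NONE


def derive_either(heroin: Recency, imf: Recency) -> Recency:
    """Most recent use of either heroin or IMF: the max under the recency order."""
    return Recency(max(int(heroin), int(imf)))


def classify_heavy_alcohol(drinks_per_week: float, sex: str) -> bool:
    """NIAAA heavy-alcohol classification: >= 15 drinks/week for men, >= 8 for women."""
    if not np.isfinite(drinks_per_week):
        raise HarmonizationError("drinks_per_week must be finite")
    if drinks_per_week < 0:
        raise HarmonizationError("drinks_per_week cannot be negative")
    try:
        threshold = HEAVY_ALCOHOL_THRESHOLD[sex]
    except KeyError:
        raise HarmonizationError(
            f"unknown sex {sex!r}; expected one of {sorted(HEAVY_ALCOHOL_THRESHOLD)}"
        ) from None
    return drinks_per_week >= threshold


def collapse_race(category: str) -> str:
    """Collapse sparse race/ethnicity categories into 'another non-Hispanic race'."""
    try:
        return RACE_COLLAPSE_MAP[category]
    except KeyError:
        raise HarmonizationError(
            f"unknown race/ethnicity {category!r}; expected one of "
            f"{sorted(RACE_COLLAPSE_MAP)}"
        ) from None


def resolve_cigarette_blank(value: object) -> str:
    """Blank cigarette-use responses are analyzed as 'not at all'."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "missing":
        return "not at all"
    if value not in CIGARETTE_LEVELS:
        raise HarmonizationError(
            f"unknown cigarette-use level {value!r}; expected one of {CIGARETTE_LEVELS} or blank"
        )
    return str(value)


# ---------------------------------------------------------------------------
# dataset-level harmonization


def recency_indicator(df: pd.DataFrame, outcome: str, recency: str) -> np.ndarray:
    """Boolean indicator for one outcome x recency analysis cell.

    ``outcome`` is heroin | imf | either; ``recency`` is past_year (any use in
    the last 12 months), past_month, or months_2_12.
    """
    col = df[f"{outcome}_recency"]
    if recency == "past_year":
        return (col != "none").to_numpy()
    if recency not in RECENCY_FROM_LABEL:
        raise HarmonizationError(f"unknown recency {recency!r}")
    return (col == recency).to_numpy()


def harmonize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Column-level harmonization shared by datasets and population tables.

    Adds/normalizes: ``race4`` (collapsed race), resolved ``cigarette_use``,
    ``heavy_alcohol`` derived from ``drinks_per_week`` where that raw item is
    present, and the derived ``either_recency``.
    """
    df = df.copy()
    n_in = len(df)

    if "race_ethnicity" in df.columns:
        df["race4"] = df["race_ethnicity"].map(lambda v: collapse_race(str(v)))
    if "cigarette_use" in df.columns:
        df["cigarette_use"] = df["cigarette_use"].map(resolve_cigarette_blank)
    if "drinks_per_week" in df.columns and "sex" in df.columns:
        df["heavy_alcohol"] = [
            classify_heavy_alcohol(d, s)
            for d, s in zip(df["drinks_per_week"].to_numpy(float), df["sex"])
        ]

    if {"heroin_recency", "imf_recency"}.issubset(df.columns):
        h = df["heroin_recency"].map(RECENCY_FROM_LABEL)
        f = df["imf_recency"].map(RECENCY_FROM_LABEL)
        if h.isna().any() or f.isna().any():
            raise HarmonizationError("unrecognized recency label in heroin/imf columns")
        either = np.maximum(h.to_numpy(int), f.to_numpy(int))
        df["either_recency"] = [Recency(v).label for v in either]

    assert len(df) == n_in, "harmonization must not drop records"
    return df


def harmonize_dataset(ds: SurveyDataset) -> SurveyDataset:
    """Apply the harmonized dictionary to a survey dataset.

    Never drops records or touches weights; record count in equals record
    count out.
    """
    return ds.with_data(harmonize_frame(ds.data), harmonized=True)
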