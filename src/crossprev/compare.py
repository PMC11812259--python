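"""Cross-survey bootstrap difference estimation.

The two surveys have fundamentally different designs (clustered probability
sample vs opt-in panel), which precludes pooling them in one model.  Instead
each survey is independently resampled with replacement B times (PSUs within
strata for the probability design, respondents for the panel), the weighted
estimate is recomputed on every replicate, and the replicate-wise difference
(survey B minus survey A) is summarized by its mean with percentile
confidence intervals.  Family-wise error over m simultaneous comparisons is
controlled by Bonferroni-corrected percentile intervals at level 1 - alpha/m.

Child seeds follow a fixed protocol: replicate b of survey s uses
``SeedSequence([seed, b, s])`` with s = 0 for survey A and 1 for survey B,
so replicate streams are independent and fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .dataset import OPTIN_PANEL, PROBABILITY_CLUSTERED, DesignError, SurveyDataset


class BootstrapError(ValueError):
    pass


@dataclass
class DifferenceEstimate:
    """Bootstrap-mean difference between two surveys for one quantity.

    All interval fields are on the same scale as the replicate differences
    passed to :func:`summarize_difference` (the pipeline reports percentage
    points).  The corrected interval [cci_low, cci_high] always contains the
    uncorrected one.
    """

    quantity: str
    diff_point: float
    ci_low: float
    ci_high: float
    cci_low: float
    cci_high: float
    B: int
    alpha: float
    m: int
    alpha_c: float
    ci_level_percent: float
    seed: int | None = None
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def bonferroni_alpha(alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni-corrected level: (alpha_c, CI level in percent to 2 d.p.).

    With alpha = 0.05 and a family of m = 43 comparisons this gives
    alpha_c = 0.05/43 ~= 0.0012 per comparison, i.e. 99.88% intervals.
    """
    if not (0.0 < alpha < 1.0):
        raise BootstrapError("alpha must be in (0, 1)")
    if m < 1:
        raise BootstrapError("comparison count m must be >= 1")
    alpha_c = alpha / m
    return alpha_c, round(100.0 * (1.0 - alpha_c), 2)


def replicate_seed(seed: int, b: int, survey_index: int) -> np.random.SeedSequence:
    """Child seed for replicate ``b`` of survey ``survey_index`` (0=A, 1=B)."""
    return np.random.SeedSequence([seed, b, survey_index])


def _draw_replicate_indices(
    rng: np.random.Generator, sizes: list[int]
) -> list[np.ndarray]:
    """One with-replacement draw of n_h units per group, in group order.

    This is the single source of bootstrap randomness: both
    :func:`resample_survey` and the vectorized estimator path call it, so
    they consume the random stream identically.
    """
    return [rng.integers(0, n_h, size=n_h) for n_h in sizes]


def _resolve_unit(ds: SurveyDataset, resample_unit: str | None) -> str:
    if resample_unit is None:
        return "psu" if ds.kind == PROBABILITY_CLUSTERED else "respondent"
    if resample_unit not in ("psu", "respondent"):
        raise BootstrapError(f"unknown resample unit {resample_unit!r}")
    if resample_unit == "psu" and ds.kind != PROBABILITY_CLUSTERED:
        raise BootstrapError("PSU resampling requires a probability_clustered design")
    return resample_unit


def _unit_groups(ds: SurveyDataset, unit: str) -> tuple[list[str], list[list[np.ndarray]]]:
    """(stratum labels, per-stratum list of unit row-position arrays), sorted."""
    if unit == "respondent":
        return ["_all"], [[np.array([i]) for i in range(ds.n)]]
    df = ds.data
    strata: list[str] = []
    groups: list[list[np.ndarray]] = []
    pos = pd.RangeIndex(len(df))
    by_stratum = pd.Series(np.arange(len(df))).groupby(
        df[ds.stratum_col].astype(str).to_numpy(), sort=True
    )
    for stratum, rows in by_stratum:
        psu_of = df[ds.psu_col].astype(str).to_numpy()[rows.to_numpy()]
        units = [
            rows.to_numpy()[psu_of == p] for p in sorted(pd.unique(psu_of))
        ]
        strata.append(stratum)
        groups.append(units)
    del pos
    return strata, groups


def resample_survey(
    ds: SurveyDataset,
    seed: int | np.random.SeedSequence,
    resample_unit: str | None = None,
) -> SurveyDataset:
    """One with-replacement bootstrap replicate of a survey.

    Probability design: within each stratum, n_h PSUs are drawn with
    replacement from the n_h sampled PSUs; a PSU drawn k times contributes k
    weight-preserving copies (relabeled to stay distinct).  Opt-in panel:
    n respondents drawn with replacement.  Weights are carried unchanged.
    """
    unit = _resolve_unit(ds, resample_unit)
    rng = np.random.default_rng(seed)
    if unit == "respondent":
        (idx,) = _draw_replicate_indices(rng, [ds.n])
        rep = ds.data.iloc[idx].reset_index(drop=True)
        return ds.with_data(rep, replicate=True)
    strata, groups = _unit_groups(ds, unit)
    picks = _draw_replicate_indices(rng, [len(g) for g in groups])
    parts: list[pd.DataFrame] = []
    for units, pick in zip(groups, picks):
        for copy_idx, j in enumerate(pick):
            block = ds.data.iloc[units[j]].copy()
            block[ds.psu_col] = block[ds.psu_col].astype(str) + f"~{copy_idx}"
            parts.append(block)
    rep = pd.concat(parts, ignore_index=True)
    return ds.with_data(rep, replicate=True)


def _indicator_matrix(
    ds: SurveyDataset, indicators: Mapping[str, object]
) -> tuple[list[str], np.ndarray]:
    cols = []
    names = list(indicators)
    for name in names:
        ind = indicators[name]
        if callable(ind):
            y = ind(ds.data)
        elif isinstance(ind, str):
            y = ds.data[ind]
        else:
            y = ind
        y = np.asarray(y, dtype=float)
        if y.shape != (ds.n,):
            raise BootstrapError(f"indicator {name!r} has wrong length")
        cols.append(y)
    return names, np.column_stack(cols)


def bootstrap_differences(
    survey_a: SurveyDataset,
    survey_b: SurveyDataset,
    indicators: Mapping[str, object],
    B: int = 2000,
    seed: int = 0,
    resample_unit_a: str | None = None,
    resample_unit_b: str | None = None,
    max_exclusion_frac: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Replicate-wise weighted-proportion differences (survey B minus survey A).

    Returns ``(diffs, info)``: ``diffs`` is a (B_kept x m) DataFrame of
    differences on the proportion scale, one column per indicator; ``info``
    records the resampling units, seed protocol, and any excluded replicates
    (a replicate is excluded if an estimate is undefined; more than
    ``max_exclusion_frac`` exclusions is a hard error).

    The per-replicate estimates are computed from per-unit weighted totals,
    which is algebraically identical to rebuilding the replicate dataset and
    calling the prevalence estimator, but runs in O(units) per replicate.
    """
    if B < 1:
        raise BootstrapError("B must be >= 1")
    unit_a = _resolve_unit(survey_a, resample_unit_a)
    unit_b = _resolve_unit(survey_b, resample_unit_b)
    prepared = []
    names_ref: list[str] | None = None
    for ds, unit in ((survey_a, unit_a), (survey_b, unit_b)):
        names, Y = _indicator_matrix(ds, indicators)
        if names_ref is None:
            names_ref = names
        w = ds.weights
        if unit == "respondent":
            prepared.append(("respondent", None, Y * w[:, None], w))
        else:
            _, groups = _unit_groups(ds, unit)
            sizes = [len(g) for g in groups]
            # per-unit totals, ordered stratum-major then PSU
            unit_rows = [u for g in groups for u in g]
            WY = np.stack([(Y[u] * w[u, None]).sum(axis=0) for u in unit_rows])
            W = np.array([w[u].sum() for u in unit_rows])
            offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1]
            prepared.append(("psu", (sizes, offsets), WY, W))

    m = len(names_ref)
    diffs = np.empty((B, m))
    excluded: list[int] = []
    for b in range(B):
        est = []
        for s, (unit, grp, WY, W) in enumerate(prepared):
            rng = np.random.default_rng(replicate_seed(seed, b, s))
            if unit == "respondent":
                (idx,) = _draw_replicate_indices(rng, [W.size])
            else:
                sizes, offsets = grp
                picks = _draw_replicate_indices(rng, sizes)
                idx = np.concatenate(
                    [off + p for off, p in zip(offsets, picks)]
                )
            tot = W[idx].sum()
            est.append(WY[idx].sum(axis=0) / tot)
        row = est[1] - est[0]
        if not np.all(np.isfinite(row)):
            excluded.append(b)
            row = np.full(m, np.nan)
        diffs[b] = row

    if len(excluded) > max_exclusion_frac * B:
        raise BootstrapError(
            f"{len(excluded)} of {B} replicates excluded (> {max_exclusion_frac:.0%})"
        )
    out = pd.DataFrame(diffs, columns=names_ref).dropna()
    info = {
        "B": B,
        "B_kept": len(out),
        "n_excluded": len(excluded),
        "excluded_replicates": excluded,
        "seed": seed,
        "resample_unit_a": unit_a,
        "resample_unit_b": unit_b,
        "direction": f"{survey_b.label} minus {survey_a.label}",
    }
    return out, info


def summarize_difference(
    diffs: np.ndarray,
    alpha: float,
    m: int,
    quantity: str = "",
    seed: int | None = None,
    n_excluded: int = 0,
) -> DifferenceEstimate:
    """Summarize a replicate difference vector.

    Point estimate is the arithmetic mean of the replicates; intervals are
    empirical quantiles (inverse empirical CDF with linear interpolation,
    numpy's default) at levels alpha/2 and alpha_c/2 with
    alpha_c = alpha / m.  The corrected interval necessarily contains the
    uncorrected one, which is asserted on every call.
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise BootstrapError("empty replicate vector")
    alpha_c, level_pct = bonferroni_alpha(alpha, m)
    point = float(diffs.mean())
    lo, hi = np.quantile(diffs, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    clo, chi = np.quantile(diffs, [alpha_c / 2.0, 1.0 - alpha_c / 2.0], method="linear")
    assert clo <= lo and chi >= hi, "corrected interval must contain the uncorrected one"
    return DifferenceEstimate(
        quantity=quantity,
        diff_point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        cci_low=float(clo),
        cci_high=float(chi),
        B=int(diffs.size),
        alpha=alpha,
        m=m,
        alpha_c=alpha_c,
        ci_level_percent=level_pct,
        seed=seed,
        n_excluded=n_excluded,
    )
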