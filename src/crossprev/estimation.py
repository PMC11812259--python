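"""Design-based weighted prevalence estimation.

Point estimates are Hajek ratio estimators p = sum(w*y)/sum(w).  Variance is
Taylor-linearized under the ultimate-cluster, with-replacement-first-stage
approximation — the de facto standard for national household-survey designs:
per-PSU score totals z_hj = sum_{i in hj} w_i (y_i - p), and

    var(p) = sum_h [n_h / (n_h - 1)] sum_j (z_hj - zbar_h)^2 / (sum_i w_i)^2.

An opt-in panel is treated as a single-stage design with each respondent as
its own sampling unit.  Confidence intervals are logit-transformed: a normal
interval for log(p/(1-p)) with the delta-method SE, back-transformed, which
keeps intervals inside (0, 1) in the sub-1% prevalence regime this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .dataset import OPTIN_PANEL, PROBABILITY_CLUSTERED, DesignError, SurveyDataset


class EstimationError(ValueError):
    pass


@dataclass
class PrevalenceEstimate:
    """Weighted proportion with design-based uncertainty for one analysis cell."""

    outcome: str
    recency: str
    survey: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    weighted_total: float
    level: float = 0.95
    ci_method: str = "logit"
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def weighted_proportion(
    y: np.ndarray, w: np.ndarray
) -> tuple[float, float, int]:
    """Hajek weighted proportion: (p_hat, weighted_total, n_unweighted)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size == 0:
        raise EstimationError("empty record collection")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise EstimationError("weights must be finite and > 0")
    total = float(w.sum())
    if total <= 0:
        raise EstimationError("zero total weight")
    return float((w * y).sum() / total), total, int(y.size)


def design_se(
    y: np.ndarray,
    w: np.ndarray,
    strata: Sequence | None = None,
    psus: Sequence | None = None,
) -> float:
    """Ultimate-cluster linearized SE of the weighted proportion.

    ``strata``/``psus`` are per-record labels; omit both for a single-stage
    design with each respondent its own unit.  A stratum represented by a
    single PSU is an error — it contributes no variance information and is
    never silently collapsed.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    p_hat, total, _ = weighted_proportion(y, w)
    u = w * (y - p_hat)

    if strata is None and psus is None:
        strata = np.zeros(y.size, dtype=int)
        psus = np.arange(y.size)
    elif strata is None or psus is None:
        raise EstimationError("provide both strata and psus, or neither")

    df = pd.DataFrame({"stratum": np.asarray(strata), "psu": np.asarray(psus), "u": u})
    z = df.groupby(["stratum", "psu"], observed=True, sort=True)["u"].sum()
    var = 0.0
    for _, zh in z.groupby(level=0, observed=True, sort=True):
        n_h = len(zh)
        if n_h < 2:
            raise DesignError(
                f"stratum {zh.index[0][0]!r} has a single PSU; design variance undefined"
            )
        var += n_h / (n_h - 1) * float(((zh - zh.mean()) ** 2).sum())
    return float(np.sqrt(var) / total)


def proportion_ci(
    p_hat: float, se: float, level: float = 0.95
) -> tuple[float, float, bool]:
    """Logit-transformed interval for a proportion.

    Returns ``(low, high, degenerate)``; ``degenerate`` flags p in {0, 1}
    (or se == 0), where the interval collapses to the point.
    """
    if not (0.0 < level < 1.0):
        raise EstimationError("confidence level must be in (0, 1)")
    if not (0.0 <= p_hat <= 1.0) or se < 0:
        raise EstimationError("need 0 <= p_hat <= 1 and se >= 0")
    if p_hat in (0.0, 1.0):
        return p_hat, p_hat, True
    if se == 0.0:
        return p_hat, p_hat, False
    z = norm.ppf(1.0 - (1.0 - level) / 2.0)
    se_logit = se / (p_hat * (1.0 - p_hat))
    lo = float(expit(logit(p_hat) - z * se_logit))
    hi = float(expit(logit(p_hat) + z * se_logit))
    return lo, hi, False


def estimate_prevalence(
    ds: SurveyDataset,
    indicator: np.ndarray | Callable[[pd.DataFrame], np.ndarray],
    outcome: str = "",
    recency: str = "",
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Full design-based prevalence estimate for one indicator on one survey."""
    y = indicator(ds.data) if callable(indicator) else np.asarray(indicator)
    w = ds.weights
    p_hat, total, n = weighted_proportion(y, w)
    if ds.kind == PROBABILITY_CLUSTERED:
        se = design_se(y, w, ds.data[ds.stratum_col], ds.data[ds.psu_col])
    elif ds.kind == OPTIN_PANEL:
        se = design_se(y, w)
    else:  # pragma: no cover - kinds validated upstream
        raise DesignError(f"unknown kind {ds.kind!r}")
    lo, hi, degenerate = proportion_ci(p_hat, se, level)
    return PrevalenceEstimate(
        outcome=outcome,
        recency=recency,
        survey=ds.label,
        p_hat=p_hat,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_unweighted=n,
        weighted_total=total,
        level=level,
        degenerate=degenerate,
    )
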