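"""Survey-weighted logistic regression with design-based inference.

Coefficients solve the weighted score equations
``sum_i w_i x_i (y_i - pi_i(beta)) = 0`` by iteratively reweighted least
squares.  The covariance is a linearized sandwich with the same
ultimate-cluster rule as the prevalence estimator: per-PSU score totals,
centered within strata, with-replacement first stage (per-respondent units
for an opt-in panel).  Adjusted odds ratios are exp(beta) with normal Wald
intervals; multicollinearity is screened with generalized variance-inflation
factors on the weighted design matrix; average marginal effects are
counterfactual weighted mean differences in predicted probability with
delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .dataset import OPTIN_PANEL, PROBABILITY_CLUSTERED, DesignError, SurveyDataset


class FitError(ValueError):
    pass


class SeparationError(FitError):
    """Complete or quasi-complete separation: coefficients diverge."""


class RankError(FitError):
    """The design matrix is rank deficient (aliased columns)."""


@dataclass
class LogisticModelResult:
    survey: str
    terms: list[tuple[str, str]]          # (covariate, level); ("(Intercept)", "")
    reference_levels: dict[str, str]
    beta: np.ndarray
    cov: np.ndarray
    aor: np.ndarray
    aor_ci_low: np.ndarray
    aor_ci_high: np.ndarray
    vif: dict[str, float]
    vif_flagged: list[str]
    converged: bool
    iterations: int
    n_used: int
    ci_method: str = "wald-normal"
    design_mode: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": [t[0] for t in self.terms],
                "level": [t[1] for t in self.terms],
                "beta": self.beta,
                "se": np.sqrt(np.diag(self.cov)),
                "aor": self.aor,
                "aor_ci_low": self.aor_ci_low,
                "aor_ci_high": self.aor_ci_high,
            }
        )


@dataclass
class AMEResult:
    term: tuple[str, str]
    ame: float
    se: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate"], d["level"] = d.pop("term")
        return d


# ---------------------------------------------------------------------------
# design matrix


def build_design_matrix(
    df: pd.DataFrame,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
) -> tuple[np.ndarray, list[tuple[str, str]], dict[str, str]]:
    """Dummy-coded design matrix with an intercept and stated reference levels.

    Categorical covariates contribute one column per non-reference level (in
    the column's category order); numeric covariates enter as-is.  Returns
    ``(X, terms, references)``.
    """
    reference_levels = dict(reference_levels or {})
    cols: list[np.ndarray] = [np.ones(len(df))]
    terms: list[tuple[str, str]] = [("(Intercept)", "")]
    for cov in covariates:
        s = df[cov]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2 and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            cols.append(s.to_numpy(dtype=float))
            terms.append((cov, ""))
            continue
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = [str(v) for v in s.cat.categories]
            s = s.astype(str)
        else:
            s = s.map(lambda v: str(v))
            levels = sorted(s.unique())
        ref = reference_levels.get(cov, levels[0])
        if str(ref) not in levels:
            raise FitError(f"reference level {ref!r} absent from covariate {cov!r}")
        reference_levels[cov] = str(ref)
        for level in levels:
            if level == str(ref):
                continue
            cols.append((s == level).to_numpy(dtype=float))
            terms.append((cov, level))
    X = np.column_stack(cols)
    return X, terms, reference_levels


def _check_rank(X: np.ndarray, terms: list[tuple[str, str]]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [terms[j] for j in piv[diag < tol]] + [terms[j] for j in piv[X.shape[1]:]]
        aliased = sorted({f"{c}={l}" if l else c for c, l in aliased})
        raise RankError(f"design matrix rank deficient; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# fitting


def fit_weighted_logit(
    ds: SurveyDataset,
    outcome: np.ndarray | str,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    deviance_rtol: float = 1e-10,
    compute_vifs: bool = True,
) -> LogisticModelResult:
    """Fit the survey-weighted logistic model and design-based covariance."""
    df = ds.data
    y = df[outcome].to_numpy(dtype=float) if isinstance(outcome, str) else np.asarray(
        outcome, dtype=float
    )
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise FitError("outcome must be binary 0/1")
    w = ds.weights
    X, terms, refs = build_design_matrix(df, covariates, reference_levels)
    _check_rank(X, terms)

    col_sd = X.std(axis=0)
    col_sd[col_sd == 0] = 1.0  # intercept

    beta = np.zeros(X.shape[1])
    deviance = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        pi = expit(eta)
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        score = X.T @ (w * (y - pi))
        new_dev = -2.0 * float(np.sum(w * (y * np.log(pi) + (1 - y) * np.log(1 - pi))))
        if np.max(np.abs(score)) < score_tol or (
            np.isfinite(deviance)
            and abs(deviance - new_dev) < deviance_rtol * (abs(deviance) + 1e-300)
        ):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
        W = w * pi * (1 - pi)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular weighted information matrix at iteration {it}") from err
        beta = beta + step
        if np.max(np.abs(beta * col_sd)) > 15.0:
            raise SeparationError(
                "coefficients diverging (|standardized beta| > 15): complete or "
                "quasi-complete separation; collapse sparse categories"
            )
    if not converged:
        raise FitError(f"IRLS did not converge in {max_iter} iterations (deviance {deviance:.6g})")

    cov = _sandwich_cov(ds, X, y, w, beta)
    se = np.sqrt(np.diag(cov))
    z = norm.ppf(0.975)
    aor = np.exp(beta)
    vifs: dict[str, float] = {}
    flagged: list[str] = []
    if compute_vifs and X.shape[1] > 2:
        vifs = compute_vif_from_matrix(X[:, 1:], terms[1:], w)
        flagged = [c for c, v in vifs.items() if v > 5.0]
    return LogisticModelResult(
        survey=ds.label,
        terms=terms,
        reference_levels=refs,
        beta=beta,
        cov=cov,
        aor=aor,
        aor_ci_low=np.exp(beta - z * se),
        aor_ci_high=np.exp(beta + z * se),
        vif=vifs,
        vif_flagged=flagged,
        converged=converged,
        iterations=it,
        n_used=len(df),
        design_mode="ultimate-cluster" if ds.kind == PROBABILITY_CLUSTERED else "respondent",
    )


def _sandwich_cov(
    ds: SurveyDataset, X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Linearized sandwich covariance with ultimate-cluster score totals."""
    pi = expit(X @ beta)
    U = X * (w * (y - pi))[:, None]  # per-record scores
    H = X.T @ (X * (w * pi * (1 - pi))[:, None])
    bread = np.linalg.inv(H)

    if ds.kind == PROBABILITY_CLUSTERED:
        strata = ds.data[ds.stratum_col].astype(str).to_numpy()
        psus = ds.data[ds.psu_col].astype(str).to_numpy()
    else:
        strata = np.zeros(len(y), dtype=int)
        psus = np.arange(len(y))

    meat = np.zeros((X.shape[1], X.shape[1]))
    dfu = pd.DataFrame(U)
    dfu["_s"] = strata
    dfu["_p"] = psus
    z = dfu.groupby(["_s", "_p"], observed=True, sort=True).sum()
    for _, zh in z.groupby(level=0, observed=True, sort=True):
        n_h = len(zh)
        if n_h < 2:
            raise DesignError(f"stratum {zh.index[0][0]!r} has a single PSU")
        resid = zh.to_numpy() - zh.to_numpy().mean(axis=0)
        meat += n_h / (n_h - 1) * resid.T @ resid
    return bread @ meat @ bread


# ---------------------------------------------------------------------------
# VIF


def compute_vif(
    ds: SurveyDataset,
    covariates: list[str],
    reference_levels: dict[str, str] | None = None,
) -> dict[str, float]:
    """Generalized VIF per covariate on the weighted design matrix."""
    X, terms, _ = build_design_matrix(ds.data, covariates, reference_levels)
    _check_rank(X, terms)
    return compute_vif_from_matrix(X[:, 1:], terms[1:], ds.weights)


def compute_vif_from_matrix(
    X: np.ndarray, terms: list[tuple[str, str]], w: np.ndarray
) -> dict[str, float]:
    """Fox-Monette generalized VIF from the weighted correlation matrix.

    For a single-column covariate this reduces to the classical
    ``1 / (1 - R^2)``.  Values are >= 1 by construction.
    """
    wn = w / w.sum()
    mu = wn @ X
    Xc = X - mu
    cov = (Xc * wn[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        bad = [terms[j] for j in np.where(sd <= 0)[0]]
        raise RankError(f"constant design columns: {bad}")
    R = cov / np.outer(sd, sd)
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0 or logdet_R < np.log(1e-12):
        raise RankError("weighted correlation matrix is singular (aliased columns)")

    covnames = []
    for c, _ in terms:
        if c not in covnames:
            covnames.append(c)
    out: dict[str, float] = {}
    for cov_name in covnames:
        own = np.array([t[0] == cov_name for t in terms])
        _, ld_own = np.linalg.slogdet(R[np.ix_(own, own)])
        _, ld_rest = np.linalg.slogdet(R[np.ix_(~own, ~own)]) if (~own).any() else (1.0, 0.0)
        out[cov_name] = float(np.exp(ld_own + ld_rest - logdet_R))
    return out


# ---------------------------------------------------------------------------
# average marginal effects


def average_marginal_effects(
    model: LogisticModelResult, ds: SurveyDataset, covariates: list[str]
) -> list[AMEResult]:
    """AME of each non-reference level vs its reference, weighted over the sample.

    For covariate X and level l: every record's X is counterfactually set to
    l and then to the reference; the AME is the weighted mean difference in
    predicted probability.  Standard errors are by the delta method through
    the design-based coefficient covariance.
    """
    if not model.converged:
        raise FitError("model did not converge; AMEs undefined")
    df = ds.data
    w = ds.weights
    wn = w / w.sum()
    z = norm.ppf(0.975)
    results: list[AMEResult] = []
    model_terms = set(model.terms)
    for cov_name in covariates:
        levels = [l for c, l in model.terms if c == cov_name and l != ""]
        if not levels:
            continue  # numeric covariate: level-shift AME not defined here
        ref = model.reference_levels[cov_name]
        for level in levels:
            if (cov_name, level) not in model_terms:
                raise FitError(f"level {level!r} of {cov_name!r} not in the model")
            X1, _, _ = build_design_matrix(
                _set_column(df, cov_name, level), covariates, model.reference_levels
            )
            X0, _, _ = build_design_matrix(
                _set_column(df, cov_name, ref), covariates, model.reference_levels
            )
            p1 = expit(X1 @ model.beta)
            p0 = expit(X0 @ model.beta)
            ame = float(wn @ (p1 - p0))
            grad = (wn * p1 * (1 - p1)) @ X1 - (wn * p0 * (1 - p0)) @ X0
            se = float(np.sqrt(grad @ model.cov @ grad))
            results.append(
                AMEResult(
                    term=(cov_name, level),
                    ame=ame,
                    se=se,
                    ci_low=ame - z * se,
                    ci_high=ame + z * se,
                )
            )
    return results


def _set_column(df: pd.DataFrame, col: str, value: str) -> pd.DataFrame:
    """Counterfactually set a categorical column, preserving its vocabulary."""
    out = df.copy()
    s = df[col]
    if isinstance(s.dtype, pd.CategoricalDtype):
        cats = [str(c) for c in s.cat.categories]
    else:
        cats = sorted(s.map(lambda v: str(v)).unique())
    if value not in cats:
        raise FitError(f"level {value!r} not a category of {col!r}")
    out[col] = pd.Categorical([value] * len(df), categories=cats)
    return out
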