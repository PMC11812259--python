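"""Survey dataset container and design metadata.

A :class:`SurveyDataset` bundles respondent-level records (a pandas
DataFrame) with the design metadata every design-based estimator needs:
the design kind, the stratum/PSU column names for a clustered probability
sample, and the analytic-weight column.  Datasets round-trip to CSV plus a
JSON sidecar so runs are fully inspectable as plain text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

PROBABILITY_CLUSTERED = "probability_clustered"
OPTIN_PANEL = "optin_panel"
_KINDS = (PROBABILITY_CLUSTERED, OPTIN_PANEL)


class DesignError(ValueError):
    """The survey design metadata is invalid for the requested operation."""


@dataclass
class SurveyDesignSpec:
    """Sampling-design parameters for the synthetic survey generator.

    For ``kind="probability_clustered"`` a stratified two-stage sample is
    drawn: ``sample_psus_per_stratum`` PSUs without replacement within each
    of ``n_strata`` strata, then ``respondents_per_psu`` persons without
    replacement within each sampled PSU, followed by logistic nonresponse
    thinning with inverse-response-rate weight adjustment.

    For ``kind="optin_panel"`` every person joins independently with
    probability ``expit(selection_model)``; weights start uniform and are
    raked to ``raking_margins``.

    ``nonresponse_model`` / ``selection_model`` map covariate name ->
    {level: log-odds}, with the special key ``"_intercept"`` -> float.
    """

    kind: str
    n_strata: int = 1
    psus_per_stratum: int = 1
    sample_psus_per_stratum: int = 1
    respondents_per_psu: int = 100
    psu_assignment: str = "random"
    nonresponse_model: dict[str, Any] | None = None
    selection_model: dict[str, Any] | None = None
    raking_margins: list[str] = field(default_factory=list)
    label: str = "survey"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DesignError(f"unknown design kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == PROBABILITY_CLUSTERED:
            if self.sample_psus_per_stratum < 2:
                raise DesignError(
                    "probability_clustered designs need >= 2 sampled PSUs per stratum "
                    "for design-based variance estimation"
                )
            if self.sample_psus_per_stratum > self.psus_per_stratum:
                raise DesignError(
                    f"cannot sample {self.sample_psus_per_stratum} PSUs from strata "
                    f"holding {self.psus_per_stratum}"
                )
        if self.kind == OPTIN_PANEL and self.selection_model is None:
            self.selection_model = {"_intercept": 0.0}

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class SurveyDataset:
    """Respondent records plus the design metadata estimators consume."""

    data: pd.DataFrame
    kind: str
    weight_col: str = "weight"
    stratum_col: str | None = None
    psu_col: str | None = None
    label: str = "survey"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DesignError(f"unknown design kind {self.kind!r}")
        if self.kind == PROBABILITY_CLUSTERED:
            if self.stratum_col is None or self.psu_col is None:
                raise DesignError("probability_clustered datasets need stratum and PSU columns")
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            raise DesignError(f"survey {self.label!r}: empty dataset")
        w = df[self.weight_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise DesignError(f"survey {self.label!r}: weights must be finite and > 0")
        if self.kind == PROBABILITY_CLUSTERED:
            counts = df.groupby(self.stratum_col, observed=True)[self.psu_col].nunique()
            bad = counts[counts < 2]
            if len(bad):
                raise DesignError(
                    f"survey {self.label!r}: strata with a single PSU "
                    f"(no variance contribution): {list(bad.index)}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def weights(self) -> np.ndarray:
        return self.data[self.weight_col].to_numpy(dtype=float)

    @property
    def weighted_total(self) -> float:
        return float(self.weights.sum())

    def with_data(self, data: pd.DataFrame, **meta: Any) -> "SurveyDataset":
        """Copy of this dataset with new records and merged metadata."""
        new_meta = {**self.meta, **meta}
        return SurveyDataset(
            data=data,
            kind=self.kind,
            weight_col=self.weight_col,
            stratum_col=self.stratum_col,
            psu_col=self.psu_col,
            label=self.label,
            meta=new_meta,
        )

    # -- I/O: CSV + JSON sidecar -----------------------------------------

    def write(self, path: str | Path) -> Path:
        """Write records to ``<path>.csv`` and design metadata to ``<path>.json``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        csv_path = path.with_suffix(".csv")
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "kind": self.kind,
            "weight_col": self.weight_col,
            "stratum_col": self.stratum_col,
            "psu_col": self.psu_col,
            "label": self.label,
            "n": self.n,
            "weighted_total": self.weighted_total,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
        return csv_path

    @classmethod
    def read(cls, path: str | Path) -> "SurveyDataset":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path.with_suffix(".csv"))
        return cls(
            data=df,
            kind=sidecar["kind"],
            weight_col=sidecar["weight_col"],
            stratum_col=sidecar["stratum_col"],
            psu_col=sidecar["psu_col"],
            label=sidecar["label"],
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj: Any) -> Any:
    """Best-effort conversion of metadata to JSON-serializable values."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
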