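"""Model-quality statistics for solubility predictions.

Conventions used throughout:

* ``r²`` — squared Pearson correlation between observed and calculated
  logS0 (slope/intercept-free; used for training, cross-validation and
  validation sets).
* ``r²_det`` — coefficient of determination about the identity line,
  ``1 − Σ(y_obs − y_calc)² / Σ(y_obs − ȳ_obs)²`` (used for external test
  sets; may be negative).
* ``MPP`` — measure of prediction performance: percentage of predictions
  within 0.5 log units of experiment (boundary inclusive).
* strong outlier — compound with |experimental − predicted| logS0 strictly
  greater than 2 log units.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SingularDesignError, UndefinedStatisticError


@dataclass
class PairedObservations:
    """Aligned experimental and calculated logS0 vectors."""

    ids: tuple[str, ...]
    y_obs: np.ndarray
    y_calc: np.ndarray

    def __post_init__(self) -> None:
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        self.y_calc = np.asarray(self.y_calc, dtype=float)
        self.ids = tuple(str(i) for i in self.ids)
        if not (len(self.ids) == len(self.y_obs) == len(self.y_calc)):
            raise UndefinedStatisticError("ids, y_obs and y_calc lengths differ")
        if not (np.isfinite(self.y_obs).all() and np.isfinite(self.y_calc).all()):
            raise UndefinedStatisticError("non-finite values in paired observations")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, obs: str = "y_obs", calc: str = "y_calc"):
        return cls(tuple(frame.index.astype(str)), frame[obs].to_numpy(), frame[calc].to_numpy())

    def concat(self, other: "PairedObservations") -> "PairedObservations":
        return PairedObservations(
            self.ids + other.ids,
            np.concatenate([self.y_obs, other.y_obs]),
            np.concatenate([self.y_calc, other.y_calc]),
        )


def _as_pair(p, y_calc=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, PairedObservations):
        return p.y_obs, p.y_calc
    return np.asarray(p, dtype=float), np.asarray(y_calc, dtype=float)


def pearson_r2(p, y_calc=None) -> float:
    """Squared Pearson correlation between observed and calculated values."""
    y_obs, y_hat = _as_pair(p, y_calc)
    if len(y_obs) < 2:
        raise UndefinedStatisticError("need at least two observations")
    do = y_obs - y_obs.mean()
    dc = y_hat - y_hat.mean()
    so, sc = float(do @ do), float(dc @ dc)
    if so == 0.0 or sc == 0.0:
        raise UndefinedStatisticError("zero variance in observed or calculated values")
    return float((do @ dc) ** 2 / (so * sc))


def rdet_test(p, y_calc=None) -> float:
    """Coefficient of determination about the identity line (test sets)."""
    y_obs, y_hat = _as_pair(p, y_calc)
    denom = float(((y_obs - y_obs.mean()) ** 2).sum())
    if denom == 0.0:
        raise UndefinedStatisticError("zero variance in observed values")
    return 1.0 - float(((y_obs - y_hat) ** 2).sum()) / denom


def rmse(p, y_calc=None) -> float:
    """Root mean square error of prediction."""
    y_obs, y_hat = _as_pair(p, y_calc)
    if len(y_obs) == 0:
        raise UndefinedStatisticError("empty observation set")
    return float(np.sqrt(np.mean((y_obs - y_hat) ** 2)))


MPP_THRESHOLD = 0.5


def mpp(p, y_calc=None) -> float:
    """Percentage of predictions within 0.5 log units (inclusive boundary)."""
    y_obs, y_hat = _as_pair(p, y_calc)
    if len(y_obs) == 0:
        raise UndefinedStatisticError("empty observation set")
    within = np.abs(y_obs - y_hat) <= MPP_THRESHOLD
    return 100.0 * float(within.sum()) / len(y_obs)


STRONG_OUTLIER_THRESHOLD = 2.0


def strong_outliers(p: PairedObservations) -> list[tuple[str, float]]:
    """Compounds with |residual| strictly above 2 log units.

    Residual is experimental − calculated.  Sorted by |residual| descending
    (ties broken by compound id).
    """
    residuals = p.y_obs - p.y_calc
    hits = [
        (cid, float(res))
        for cid, res in zip(p.ids, residuals)
        if abs(res) > STRONG_OUTLIER_THRESHOLD
    ]
    return sorted(hits, key=lambda t: (-abs(t[1]), t[0]))


def loo_cv(X, y, fit: Callable | None = None) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation of an OLS model.

    Refits on every n−1 subset (through ``fit``, default the package OLS)
    and predicts the held-out compound; returns the squared Pearson
    correlation of observed vs LOO-predicted values and the predictions.
    """
    from .models import fit_mlr

    fit = fit or fit_mlr
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 2:
        raise UndefinedStatisticError(f"n={n} too small for LOO with p={p}")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            res = fit(X[mask], y[mask])
        except SingularDesignError as exc:
            raise SingularDesignError(detail=f"leave-one-out fold {i}: {exc}") from exc
        preds[i] = float(res.predict(X[i : i + 1])[0])
        mask[i] = True
    return pearson_r2(y, preds), preds


@dataclass
class EvaluationReport:
    """Bundle of quality statistics for one evaluation run."""

    n: int
    r2: float
    rdet2: Optional[float]
    rmse: float
    mpp: float
    rcv2: Optional[float] = None
    strong_outliers: list[tuple[str, float]] = field(default_factory=list)
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "r2": self.r2,
            "rdet2": self.rdet2,
            "rmse": self.rmse,
            "mpp": self.mpp,
            "rcv2": self.rcv2,
            "n_strong_outliers": len(self.strong_outliers),
            "strong_outliers": [
                {"id": cid, "residual": res} for cid, res in self.strong_outliers
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def csv_row(self) -> str:
        """Flat CSV row (header + values) at paper-style reporting precision."""
        header = "label,n,r2,rdet2,rmse,mpp,rcv2,n_strong_outliers"
        fmt = lambda v, nd=2: "" if v is None else f"{round(v, nd):.{nd}f}"
        values = ",".join(
            [
                self.label,
                str(self.n),
                fmt(self.r2),
                fmt(self.rdet2),
                fmt(self.rmse),
                "" if self.mpp is None else f"{self.mpp:.0f}",
                fmt(self.rcv2),
                str(len(self.strong_outliers)),
            ]
        )
        return f"{header}\n{values}"

    def summary(self) -> str:
        parts = [f"n = {self.n}", f"R² = {self.r2:.2f}"]
        if self.rdet2 is not None:
            parts.append(f"R²det = {self.rdet2:.2f}")
        if self.rcv2 is not None:
            parts.append(f"R²cv = {self.rcv2:.2f}")
        parts += [f"RMSE = {self.rmse:.2f}", f"MPP = {self.mpp:.0f}%",
                  f"strong outliers = {len(self.strong_outliers)}"]
        label = f"[{self.label}] " if self.label else ""
        return label + ", ".join(parts)


def evaluate_pairs(
    pairs: PairedObservations | Sequence[PairedObservations],
    label: str = "",
    include_rdet: bool = True,
) -> EvaluationReport:
    """Compute an :class:`EvaluationReport` from paired observations.

    A sequence of paired sets is concatenated first (merged-set analysis),
    which is by construction identical to evaluating the concatenation.
    """
    if not isinstance(pairs, PairedObservations):
        sets = list(pairs)
        if not sets:
            raise UndefinedStatisticError("no observation sets to evaluate")
        merged = sets[0]
        for extra in sets[1:]:
            merged = merged.concat(extra)
        pairs = merged
    if len(pairs) == 0:
        raise UndefinedStatisticError("empty dataset")
    return EvaluationReport(
        n=len(pairs),
        r2=pearson_r2(pairs),
        rdet2=rdet_test(pairs) if include_rdet else None,
        rmse=rmse(pairs),
        mpp=mpp(pairs),
        strong_outliers=strong_outliers(pairs),
        label=label,
    )


def evaluate(model, dataset, descriptor_matrix, label: str = "") -> EvaluationReport:
    """Evaluate a :class:`~intrinsol.models.LinearSolubilityModel` on a dataset.

    ``dataset`` is an iterable of molecule records with experimental values;
    descriptor values come from ``descriptor_matrix`` (a
    :class:`~intrinsol.descriptors.DescriptorMatrix` or DataFrame).
    """
    frame = getattr(descriptor_matrix, "frame", descriptor_matrix)
    ids, y_obs, y_calc = [], [], []
    for rec in dataset:
        if rec.logS0_exp is None:
            continue
        pred = model.predict(frame.loc[rec.id])
        ids.append(rec.id)
        y_obs.append(rec.logS0_exp)
        y_calc.append(pred)
    if not ids:
        raise UndefinedStatisticError("no records with experimental values")
    pairs = PairedObservations(tuple(ids), np.array(y_obs), np.array(y_calc))
    return evaluate_pairs(pairs, label=label or model.name)
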