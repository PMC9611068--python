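"""Multilinear QSPR models for intrinsic aqueous solubility.

Two object kinds live here, mirroring the statsmodels split between a model
and its results:

* :class:`LinearSolubilityModel` — a fixed linear predictor
  ``logS0 = intercept + Σ βᵢ·descriptorᵢ``.  The three published solubility
  models (M1–M3) ship as registry constants, and any fitted model can be
  archived to / restored from JSON.
* :class:`SolubilityMLR` / :class:`MLRResults` — ordinary least squares fit
  of a new model to a descriptor matrix, with coefficient standard errors,
  t-values, leverage diagnostics, leave-one-out statistics and a summary
  table.

The consensus predictor averages the predictions of several member models
at full floating precision; rounding (2 dp, round-half-to-even) happens
only at reporting time.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ArchiveError,
    ConsensusUndefinedError,
    MissingDescriptorError,
    SingularDesignError,
)

SCHEMA_VERSION = 1
PROPERTY_LABEL = "logS0[log10 M]"


def report_round(value: float, ndigits: int = 2) -> float:
    """Reporting precision: round-half-to-even (Python's built-in round)."""
    return round(value, ndigits)


@dataclass(frozen=True)
class LinearSolubilityModel:
    """A multilinear logS0 model: named descriptors, coefficients, intercept."""

    name: str
    descriptor_names: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.descriptor_names) != len(self.coefficients):
            raise ArchiveError(
                f"{self.name}: {len(self.coefficients)} coefficients for "
                f"{len(self.descriptor_names)} descriptors"
            )
        values = (*self.coefficients, self.intercept)
        if not all(math.isfinite(v) for v in values):
            raise ArchiveError(f"{self.name}: non-finite parameters")

    # -- prediction ---------------------------------------------------------
    def predict(self, x: Mapping[str, float] | pd.Series) -> float:
        """Predict logS0 for one compound from a descriptor mapping."""
        total = self.intercept
        for name, beta in zip(self.descriptor_names, self.coefficients):
            if name not in x:
                raise MissingDescriptorError(name, self.name)
            value = float(x[name])
            if not math.isfinite(value):
                raise MissingDescriptorError(name, self.name)
            total += beta * value
        return total

    def predict_frame(self, frame: pd.DataFrame) -> pd.Series:
        """Vectorized prediction; rows with missing descriptors yield NaN."""
        missing_cols = [n for n in self.descriptor_names if n not in frame.columns]
        if missing_cols:
            raise MissingDescriptorError(missing_cols[0], self.name)
        X = frame[list(self.descriptor_names)].to_numpy(dtype=float)
        pred = self.intercept + X @ np.asarray(self.coefficients)
        pred = np.where(np.isfinite(X).all(axis=1), pred, np.nan)
        return pd.Series(pred, index=frame.index, name=self.name)

    # -- archive ------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "property": PROPERTY_LABEL,
            "descriptors": [
                {"name": n, "coefficient": c}
                for n, c in zip(self.descriptor_names, self.coefficients)
            ],
            "intercept": self.intercept,
            "metadata": dict(self.metadata),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "LinearSolubilityModel":
        try:
            version = payload["schema_version"]
        except (KeyError, TypeError) as exc:
            raise ArchiveError("model archive lacks schema_version") from exc
        if version != SCHEMA_VERSION:
            raise ArchiveError(f"unknown model archive schema version {version!r}")
        descriptors = payload["descriptors"]
        return cls(
            name=str(payload["name"]),
            descriptor_names=tuple(d["name"] for d in descriptors),
            coefficients=tuple(float(d["coefficient"]) for d in descriptors),
            intercept=float(payload["intercept"]),
            metadata=dict(payload.get("metadata", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearSolubilityModel":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ArchiveError(f"malformed model archive {path}: {exc}") from exc
        return cls.from_dict(payload)


# ---------------------------------------------------------------------------
# Published model registry
# ---------------------------------------------------------------------------

M1 = LinearSolubilityModel(
    name="M1",
    descriptor_names=("SM04_EA_bo", "ALOGP2"),
    coefficients=(-1.64547, -0.0935641),
    intercept=8.3304,
    metadata={
        "n_train": 81,
        "r2_train": 0.67, "r2_cv": 0.64, "rmse_train": 0.82,
        "n_val": 42, "r2_val": 0.79, "rmse_val": 0.85,
        "training_set": "small high-consensus CheqSol compilation",
        "selection": "stepwise forward (BMLR)",
    },
)

M2 = LinearSolubilityModel(
    name="M2",
    descriptor_names=("TPSA", "MolLogP"),
    coefficients=(-0.01662, -0.84928),
    intercept=-0.3583,
    metadata={
        "n_train": 346,
        "r2_train": 0.62, "r2_cv": 0.62, "rmse_train": 1.00,
        "n_val": 90, "r2_val": 0.69, "rmse_val": 0.98,
        "training_set": "large structurally diverse compilation",
        "selection": "orthogonal matching pursuit",
    },
)

M3 = LinearSolubilityModel(
    name="M3",
    descriptor_names=("XlogS", "SpMax1_Bhp", "SHBd"),
    coefficients=(0.82617, -2.71151, -0.50016),
    intercept=9.14318,
    metadata={
        "n_train": 346,
        "r2_train": 0.67, "r2_cv": 0.66, "rmse_train": 0.94,
        "n_val": 90, "r2_val": 0.78, "rmse_val": 0.84,
        "training_set": "large structurally diverse compilation",
        "selection": "random-forest preselection + exhaustive search",
    },
)

MODEL_REGISTRY: Mapping[str, LinearSolubilityModel] = {"M1": M1, "M2": M2, "M3": M3}


def get_model(name_or_path: str) -> LinearSolubilityModel:
    """Resolve a registry name (M1/M2/M3) or a JSON archive path."""
    if name_or_path in MODEL_REGISTRY:
        return MODEL_REGISTRY[name_or_path]
    path = Path(name_or_path)
    if path.exists():
        return LinearSolubilityModel.from_json(path)
    raise ArchiveError(f"unknown model {name_or_path!r} (not a registry name or file)")


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Per-compound prediction record: member predictions plus consensus."""

    compound_id: str
    member_predictions: dict[str, float]
    consensus: float
    excluded_members: tuple[str, ...] = ()
    residual: Optional[float] = None
    flags: dict[str, bool] = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {k: report_round(v, ndigits) for k, v in self.member_predictions.items()}
        out["consensus"] = report_round(self.consensus, ndigits)
        return out


def consensus_of(predictions: Mapping[str, float] | Sequence[float]) -> float:
    """Unweighted mean of member predictions at full precision."""
    values = list(predictions.values()) if isinstance(predictions, Mapping) else list(predictions)
    if not values:
        raise ConsensusUndefinedError("no member predictions to average")
    return float(np.mean(values))


def predict_consensus(
    members: Sequence[LinearSolubilityModel],
    x: Mapping[str, float],
    compound_id: str = "",
    y_obs: float | None = None,
) -> PredictionResult:
    """Average the predictions of all members able to predict ``x``.

    Members whose descriptors are unavailable (absent or non-finite) are
    excluded from the mean and listed in the result.
    """
    predictions: dict[str, float] = {}
    excluded: list[str] = []
    for model in members:
        try:
            predictions[model.name] = model.predict(x)
        except MissingDescriptorError:
            excluded.append(model.name)
    if not predictions:
        raise ConsensusUndefinedError(
            f"no consensus member could predict compound {compound_id!r}"
        )
    consensus = consensus_of(predictions)
    residual = None if y_obs is None else float(y_obs) - consensus
    return PredictionResult(
        compound_id=compound_id,
        member_predictions=predictions,
        consensus=consensus,
        excluded_members=tuple(excluded),
        residual=residual,
    )


# ---------------------------------------------------------------------------
# OLS fitting, statsmodels-style
# ---------------------------------------------------------------------------

def _dependent_columns(Z: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns involved in a linear dependency (for error messages)."""
    rank = np.linalg.matrix_rank(Z)
    culprits = []
    for j in range(Z.shape[1]):
        reduced = np.delete(Z, j, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            culprits.append(names[j])
    return culprits


class SolubilityMLR:
    """Ordinary least squares model ``y = intercept + Xβ`` for logS0.

    Parameters
    ----------
    y : array-like, shape (n,)
        Response (experimental logS0, log10 molar).
    X : DataFrame or array-like, shape (n, p)
        Descriptor values; column names become descriptor names.
    descriptor_names : sequence of str, optional
        Required when ``X`` is a bare array.
    """

    def __init__(self, y, X, descriptor_names: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame):
            self.descriptor_names = tuple(str(c) for c in X.columns)
            self._index = list(X.index)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.descriptor_names = tuple(
                descriptor_names or (f"x{i + 1}" for i in range(X.shape[1]))
            )
            self._index = list(range(X.shape[0]))
        self.X = X
        self.y = np.asarray(y, dtype=float)
        if self.y.shape[0] != self.X.shape[0]:
            raise SingularDesignError(detail="y and X row counts differ")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise SingularDesignError(detail="non-finite values in design or response")
        self.nobs, self.k_exog = self.X.shape

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str = "logS0",
        descriptors: Sequence[str] | None = None,
    ) -> "SolubilityMLR":
        descriptors = list(descriptors or [c for c in data.columns if c != response])
        return cls(data[response], data[descriptors])

    def fit(self) -> "MLRResults":
        n, p = self.nobs, self.k_exog
        if n <= p + 1:
            raise SingularDesignError(detail=f"n={n} too small for p={p} descriptors")
        Z = np.column_stack([np.ones(n), self.X])
        names = ("intercept", *self.descriptor_names)
        if np.linalg.matrix_rank(Z) < p + 1:
            raise SingularDesignError(columns=_dependent_columns(Z, names))
        beta, *_ = np.linalg.lstsq(Z, self.y, rcond=None)
        return MLRResults(self, beta)


class MLRResults:
    """OLS fit results: estimates, uncertainties, diagnostics, summary."""

    def __init__(self, model: SolubilityMLR, beta: np.ndarray):
        self.model = model
        n, p = model.nobs, model.k_exog
        Z = np.column_stack([np.ones(n), model.X])
        self._Z = Z
        self.params = pd.Series(beta, index=("intercept", *model.descriptor_names))
        self.fittedvalues = Z @ beta
        self.resid = model.y - self.fittedvalues
        self.df_resid = n - p - 1
        self.ssr = float(self.resid @ self.resid)
        self.scale = self.ssr / self.df_resid if self.df_resid > 0 else math.nan
        self._xtx_inv = np.linalg.inv(Z.T @ Z)
        self.bse = pd.Series(
            np.sqrt(np.diag(self._xtx_inv) * self.scale), index=self.params.index
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues = self.params / self.bse

    # -- scalar diagnostics --------------------------------------------------
    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def rsquared(self) -> float:
        y = self.model.y
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - self.ssr / tss

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    @property
    def leverage(self) -> np.ndarray:
        """Hat-matrix diagonal of the training design."""
        return np.einsum("ij,jk,ik->i", self._Z, self._xtx_inv, self._Z)

    def loo_predictions(self) -> np.ndarray:
        """Leave-one-out predictions via the hat-matrix identity."""
        h = self.leverage
        return self.fittedvalues - h * self.resid / (1.0 - h)

    def rsquared_cv(self) -> float:
        from .evaluation import pearson_r2  # local import avoids a cycle

        return pearson_r2(self.model.y, self.loo_predictions())

    # -- conversion / reporting ----------------------------------------------
    def as_model(self, name: str = "fitted", metadata: Mapping | None = None) -> LinearSolubilityModel:
        meta = {
            "n_train": self.nobs,
            "r2_train": self.rsquared,
            "rmse_train": self.rmse,
        }
        meta.update(metadata or {})
        return LinearSolubilityModel(
            name=name,
            descriptor_names=self.model.descriptor_names,
            coefficients=tuple(float(b) for b in self.params.iloc[1:]),
            intercept=float(self.params.iloc[0]),
            metadata=meta,
        )

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.model.descriptor_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.params.iloc[0] + X @ self.params.iloc[1:].to_numpy()

    def summary(self) -> str:
        lines = [
            "Ordinary least squares: logS0 [log10 M]",
            f"n = {self.nobs}, descriptors = {self.model.k_exog}",
            f"R² = {self.rsquared:.2f}, RMSE = {self.rmse:.2f}",
            "",
            f"{'term':<14}{'coef':>12}{'std err':>12}{'t':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<14}{self.params[name]:>12.5g}{self.bse[name]:>12.3g}"
                f"{self.tvalues[name]:>10.2f}"
            )
        return "\n".join(lines)


def fit_mlr(
    X, y, descriptor_names: Sequence[str] | None = None
) -> MLRResults:
    """Fit an OLS model (convenience wrapper around :class:`SolubilityMLR`)."""
    return SolubilityMLR(y, X, descriptor_names=descriptor_names).fit()
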