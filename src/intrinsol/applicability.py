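"""Applicability-domain analysis: leverage, Williams-plot data, range checks.

The applicability domain of a descriptor-based model is assessed two ways:

* **Leverage** ``h = x'(X'X)⁻¹x`` against the training design (with
  intercept).  A query above the warning leverage ``h* = 3(p+1)/n`` is
  structurally atypical relative to the training set.  Combined with raw
  residuals this yields the Williams plot.
* **Descriptor ranges** — per-descriptor closed-interval ``[min, max]``
  check of query values against the training set.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SingularDesignError
from .evaluation import STRONG_OUTLIER_THRESHOLD


def _design(X) -> np.ndarray:
    X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def leverages(X_train, X_query=None) -> np.ndarray:
    """Leverage of query points against the training design.

    With ``X_query=None`` returns the hat-matrix diagonal of the training
    set itself (which sums to the number of model parameters, p+1).
    """
    Zt = _design(X_train)
    if np.linalg.matrix_rank(Zt) < Zt.shape[1]:
        raise SingularDesignError(detail="training design is rank deficient")
    Zq = Zt if X_query is None else _design(X_query)
    if Zq.shape[1] != Zt.shape[1]:
        raise SingularDesignError(detail="query and training descriptor counts differ")
    xtx_inv = np.linalg.inv(Zt.T @ Zt)
    return np.einsum("ij,jk,ik->i", Zq, xtx_inv, Zq)


def critical_leverage(n: int, p: int) -> float:
    """Warning leverage ``h* = 3(p+1)/n`` (p descriptors plus intercept)."""
    if n <= p + 1:
        raise SingularDesignError(detail=f"n={n} too small for p={p} descriptors")
    return 3.0 * (p + 1) / n


def range_check(train, query) -> tuple[pd.DataFrame, pd.Series]:
    """Per-descriptor closed-interval range check of query against training.

    Returns a boolean DataFrame (True = inside ``[train min, train max]``)
    aligned to the query rows, and a per-descriptor count of out-of-range
    query compounds.
    """
    train = train.frame if hasattr(train, "frame") else pd.DataFrame(train)
    query = query.frame if hasattr(query, "frame") else pd.DataFrame(query)
    cols = [c for c in train.columns if c in query.columns]
    lo, hi = train[cols].min(), train[cols].max()
    inside = (query[cols] >= lo) & (query[cols] <= hi)
    return inside, (~inside).sum()


@dataclass
class ADReport:
    """Williams-plot data plus range-check flags for one model."""

    table: pd.DataFrame  # columns: id, set, leverage, residual, high_leverage, strong_outlier
    h_star: float
    descriptor_ranges: pd.DataFrame  # index: descriptor, columns: min, max
    in_range: Optional[pd.DataFrame] = None  # per-compound per-descriptor flags

    def to_dict(self) -> dict:
        recs = self.table.replace({np.nan: None}).to_dict(orient="records")
        return {
            "h_star": self.h_star,
            "residual_threshold": STRONG_OUTLIER_THRESHOLD,
            "descriptor_ranges": {
                d: {"min": float(r["min"]), "max": float(r["max"])}
                for d, r in self.descriptor_ranges.iterrows()
            },
            "compounds": recs,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def williams_csv(self, path: str | Path) -> None:
        """Plot-ready table (id, set, leverage, residual) for external plotting."""
        self.table[["id", "set", "leverage", "residual"]].to_csv(path, index=False)


def williams_data(
    model,
    train_matrix,
    train_obs: Mapping[str, float] | pd.Series | None = None,
    query_sets: Mapping[str, tuple] | None = None,
) -> ADReport:
    """Assemble Williams-plot data for a linear model.

    Parameters
    ----------
    model : LinearSolubilityModel
    train_matrix : DescriptorMatrix or DataFrame indexed by compound id
        Training descriptor values (must cover the model descriptors).
    train_obs : mapping id → experimental logS0, optional
    query_sets : mapping set label → (matrix, obs-mapping-or-None), optional

    Residuals are raw differences experimental − predicted; compounds
    without experimental values get leverage but no residual/outlier flag.
    """
    cols = list(model.descriptor_names)
    tframe = (train_matrix.frame if hasattr(train_matrix, "frame") else train_matrix)[cols]
    n, p = tframe.shape
    h_star = critical_leverage(n, p)

    rows: list[dict] = []

    def add_set(label: str, frame: pd.DataFrame, obs) -> None:
        h = leverages(tframe, None if frame is tframe else frame)
        preds = model.predict_frame(frame)
        obs = {} if obs is None else dict(obs)
        for cid, hi, pred in zip(frame.index, h, preds):
            y = obs.get(cid)
            residual = None if y is None else float(y) - float(pred)
            rows.append(
                {
                    "id": str(cid),
                    "set": label,
                    "leverage": float(hi),
                    "residual": residual,
                    "high_leverage": bool(hi > h_star),
                    "strong_outlier": (
                        None if residual is None
                        else bool(abs(residual) > STRONG_OUTLIER_THRESHOLD)
                    ),
                }
            )

    add_set("train", tframe, train_obs)
    for label, (matrix, obs) in (query_sets or {}).items():
        qframe = (matrix.frame if hasattr(matrix, "frame") else matrix)[cols]
        add_set(label, qframe, obs)

    table = pd.DataFrame(rows).sort_values(["set", "id"], kind="stable").reset_index(drop=True)
    ranges = pd.DataFrame({"min": tframe.min(), "max": tframe.max()})
    ranges.index.name = "descriptor"
    in_range = None
    if query_sets:
        qframes = [
            (m.frame if hasattr(m, "frame") else m)[cols] for m, _ in query_sets.values()
        ]
        in_range, _ = range_check(tframe, pd.concat(qframes))
    return ADReport(table=table, h_star=h_star, descriptor_ranges=ranges, in_range=in_range)
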