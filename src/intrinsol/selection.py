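"""Descriptor-selection workflows for multilinear solubility models.

Three workflows are provided, one per published model:

* :func:`bmlr_forward` — stepwise forward selection: eliminate descriptors
  with missing values and insignificant univariate regressions, then grow
  the model greedily by R² under a pairwise collinearity cap.
* :func:`omp_select` — orthogonal matching pursuit: repeatedly pick the
  descriptor most correlated with the current residual and refit OLS on the
  active set; :func:`omp_choose_k` picks the model size at which a further
  descriptor yields only a minor R² improvement.
* :func:`rf_exhaustive` — random-forest preselection (many seeded forests,
  permutation variable importance, frequency filter on per-run top lists)
  followed by an exhaustive OLS search over all small descriptor subsets.

All workflows are deterministic given (X, y, config, seed) and record a
step-by-step trace sufficient to replay the selection.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .errors import EmptySelectionError, RankError
from .models import LinearSolubilityModel, MLRResults, fit_mlr


@dataclass(frozen=True)
class SelectionConfig:
    """Tunable parameters of the selection workflows."""

    max_descriptors: int = 3
    collinearity_cap: float = 0.6        # BMLR pairwise |R| cap among selected
    t_threshold: float = 2.0             # BMLR univariate significance cutoff
    min_delta_r2: float = 0.01           # BMLR greedy stopping increment (R² units)
    omp_improvement_epsilon: float = 0.02
    rf_runs: int = 100
    rf_trees: int = 500
    rf_top_k: int = 10
    rf_frequency_threshold: int = 5      # strict >, i.e. "over five times"
    exhaustive_max_size: int = 3
    ranking_criterion: str = "r2"        # or "rcv2"
    seed: int = 0


@dataclass
class SelectionResult:
    """Outcome of one selection workflow (or one ranked candidate model)."""

    method: str
    selected: tuple[str, ...]
    model: Optional[LinearSolubilityModel]
    results: Optional[MLRResults]
    score: float
    trace: list = field(default_factory=list)
    config: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected": list(self.selected),
            "score": self.score,
            "model": None if self.model is None else self.model.to_dict(),
            "trace": self.trace,
            "config": asdict(self.config),
            "seed": self.seed,
        }


def _fit(X: pd.DataFrame, y, names: Sequence[str]) -> MLRResults:
    return fit_mlr(X[list(names)], np.asarray(y, dtype=float))


def _intercept_only(y) -> LinearSolubilityModel:
    return LinearSolubilityModel(
        "intercept-only", (), (), float(np.mean(y)), {"note": "k=0 model"}
    )


# ---------------------------------------------------------------------------
# BMLR-style stepwise forward selection
# ---------------------------------------------------------------------------

def _univariate_t(x: np.ndarray, y: np.ndarray) -> float:
    """|t| statistic of the slope in a one-descriptor regression."""
    n = len(y)
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return math.inf
    return abs(r) * math.sqrt((n - 2) / (1.0 - r2))


def bmlr_forward(X: pd.DataFrame, y, config: SelectionConfig | None = None) -> SelectionResult:
    """Stepwise forward descriptor selection with collinearity control.

    Steps: (i) drop columns with missing values; (ii) drop columns whose
    one-descriptor regression is insignificant (|t| below the threshold);
    (iii) greedily add the descriptor maximizing R² among candidates whose
    pairwise |R| with every already-selected descriptor stays within the
    collinearity cap.  Stops at ``max_descriptors`` or when the R² gain
    falls below ``min_delta_r2``.  Ties break lexicographically.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    trace: list = []

    complete = [c for c in X.columns if not X[c].isna().any()]
    dropped_missing = [c for c in X.columns if c not in complete]
    if dropped_missing:
        trace.append({"step": "drop_missing", "dropped": dropped_missing})

    admissible = []
    tstats = {}
    for c in complete:
        t = _univariate_t(X[c].to_numpy(dtype=float), y)
        tstats[c] = t
        if t >= config.t_threshold:
            admissible.append(c)
    trace.append({"step": "significance_filter", "t_threshold": config.t_threshold,
                  "t_stats": tstats, "admissible": list(admissible)})
    if not admissible:
        raise EmptySelectionError("no descriptor passes the significance filter")

    corr = X[complete].corr()
    selected: list[str] = []
    best_results: Optional[MLRResults] = None
    best_r2 = 0.0
    per_size: dict[int, tuple[tuple[str, ...], float]] = {}

    while len(selected) < config.max_descriptors:
        candidates = [
            c for c in admissible
            if c not in selected
            and all(abs(corr.loc[c, s]) <= config.collinearity_cap for s in selected)
        ]
        if not candidates:
            break
        scores: dict[str, float] = {}
        fits: dict[str, MLRResults] = {}
        for c in sorted(candidates):
            res = _fit(X, y, selected + [c])
            scores[c] = res.rsquared
            fits[c] = res
        pick = max(sorted(scores), key=lambda c: scores[c])  # lexicographic tie-break
        gain = scores[pick] - best_r2
        trace.append({"step": f"forward_{len(selected) + 1}", "scores": scores,
                      "picked": pick, "delta_r2": gain})
        if selected and gain < config.min_delta_r2:
            break
        selected.append(pick)
        best_results = fits[pick]
        best_r2 = scores[pick]
        per_size[len(selected)] = (tuple(selected), best_r2)

    assert best_results is not None
    trace.append({"step": "per_size_best",
                  "models": {k: {"selected": list(v[0]), "r2": v[1]} for k, v in per_size.items()}})
    model = best_results.as_model(name="BMLR", metadata={"method": "bmlr_forward"})
    return SelectionResult(
        method="bmlr", selected=tuple(selected), model=model, results=best_results,
        score=best_r2, trace=trace, config=config, seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Orthogonal matching pursuit
# ---------------------------------------------------------------------------

def omp_select(X: pd.DataFrame, y, k: int, config: SelectionConfig | None = None) -> SelectionResult:
    """Classic orthogonal matching pursuit with OLS refits on the active set.

    Columns are standardized internally for the correlation step; the
    returned model is on the original descriptor scale.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    names = [str(c) for c in X.columns]
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A - A.mean(axis=0))
    if k > rank:
        raise RankError(f"k={k} exceeds descriptor-matrix rank {rank}")
    if k == 0:
        return SelectionResult(
            method="omp", selected=(), model=_intercept_only(y), results=None,
            score=0.0, trace=[{"step": "k0"}], config=config, seed=config.seed,
        )

    mu, sd = A.mean(axis=0), A.std(axis=0)
    usable = sd > 0
    Astd = np.zeros_like(A)
    Astd[:, usable] = (A[:, usable] - mu[usable]) / sd[usable]

    active: list[str] = []
    residual = y - y.mean()
    trace: list = []
    results: Optional[MLRResults] = None
    for step in range(k):
        scores = {
            names[j]: (abs(float(Astd[:, j] @ residual)) if usable[j] else 0.0)
            for j in range(len(names))
            if names[j] not in active
        }
        pick = max(sorted(scores), key=lambda c: scores[c])
        active.append(pick)
        results = _fit(X, y, active)
        residual = y - results.predict(X[active])
        trace.append({"step": step + 1, "scores": scores, "picked": pick,
                      "r2": results.rsquared})
    assert results is not None
    model = results.as_model(name="OMP", metadata={"method": "omp", "k": k})
    return SelectionResult(
        method="omp", selected=tuple(active), model=model, results=results,
        score=results.rsquared, trace=trace, config=config, seed=config.seed,
    )


def choose_k_from_r2(r2_by_k: Sequence[float], epsilon: float) -> int:
    """Smallest k with R²(k+1) − R²(k) < ε; the largest k if never satisfied.

    ``r2_by_k[i]`` is the R² of the model with i+1 descriptors.
    """
    for k in range(1, len(r2_by_k)):
        if r2_by_k[k] - r2_by_k[k - 1] < epsilon:
            return k
    return len(r2_by_k)


def omp_choose_k(
    X: pd.DataFrame, y, k_max: int, epsilon: float | None = None,
    config: SelectionConfig | None = None,
) -> int:
    """Pick the OMP model size where one more descriptor adds little R²."""
    config = config or SelectionConfig()
    epsilon = config.omp_improvement_epsilon if epsilon is None else epsilon
    r2_by_k = [omp_select(X, y, k, config).score for k in range(1, k_max + 1)]
    return choose_k_from_r2(r2_by_k, epsilon)


# ---------------------------------------------------------------------------
# RF preselection + exhaustive search
# ---------------------------------------------------------------------------

def rf_exhaustive(
    X: pd.DataFrame, y, config: SelectionConfig | None = None
) -> list[SelectionResult]:
    """Random-forest descriptor preselection followed by exhaustive OLS search.

    ``rf_runs`` forests are trained with distinct derived seeds; for each,
    the ``rf_top_k`` descriptors by permutation variable importance are set
    aside.  Descriptors appearing in strictly more than
    ``rf_frequency_threshold`` of the per-run top lists survive to an
    exhaustive OLS search over all subsets of size 1..``exhaustive_max_size``,
    ranked by the configured criterion (final model choice by descriptor
    interpretability is left to the scientist — the ranked list is returned).
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    names = [str(c) for c in X.columns]
    A = X.to_numpy(dtype=float)

    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.rf_runs) % (2**31)
    counts: Counter[str] = Counter()
    top_lists: list[list[str]] = []
    for run in range(config.rf_runs):
        seed = int(child_seeds[run])
        forest = RandomForestRegressor(
            n_estimators=config.rf_trees, random_state=seed, n_jobs=1
        )
        forest.fit(A, y)
        imp = permutation_importance(
            forest, A, y, n_repeats=1, random_state=seed, n_jobs=1
        ).importances_mean
        ranked = sorted(zip(names, imp), key=lambda t: (-t[1], t[0]))
        top = [name for name, _ in ranked[: config.rf_top_k]]
        top_lists.append(top)
        counts.update(top)  # one count per run (per-run top lists are unique)

    survivors = sorted(c for c in counts if counts[c] > config.rf_frequency_threshold)
    trace: list = [
        {"step": "rf_preselection", "runs": config.rf_runs, "top_k": config.rf_top_k,
         "frequencies": dict(sorted(counts.items())), "survivors": survivors,
         "per_run_top": top_lists},
    ]
    if not survivors:
        raise EmptySelectionError(
            f"no descriptor appears in more than {config.rf_frequency_threshold} RF runs"
        )

    ranked_models: list[SelectionResult] = []
    max_size = min(config.exhaustive_max_size, len(survivors))
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(survivors, size):
            res = _fit(X, y, combo)
            score = res.rsquared if config.ranking_criterion == "r2" else res.rsquared_cv()
            ranked_models.append(
                SelectionResult(
                    method="rf-exhaustive", selected=combo,
                    model=res.as_model(name="RF+exhaustive",
                                       metadata={"method": "rf_exhaustive"}),
                    results=res, score=score, trace=trace, config=config,
                    seed=config.seed,
                )
            )
    ranked_models.sort(key=lambda r: (-r.score, r.selected))
    return ranked_models
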