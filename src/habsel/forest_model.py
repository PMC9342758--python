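"""Used-vs-available ensemble classifier with OOB tuning and importances.

Trees are CART (Gini) decision trees grown on without-replacement subsamples
of the training rows, choosing the best of ``mtry`` randomly drawn predictors
at each split.  The propensity score of a row is the fraction of trees voting
"used"; out-of-bag (OOB) error, grid tuning, and permutation importance all
operate on each tree's held-out rows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .covariates import GRID_NAMES

__all__ = [
    "PREDICTORS",
    "DEFAULT_FRACTION",
    "ForestConfig",
    "FittedForest",
    "TuningResult",
    "fit_forest",
    "tune",
    "default_grid",
    "permutation_importance",
    "predict_propensity",
    "design_matrix",
]

#: Model predictors: the eight covariate bands plus the sex indicator.
PREDICTORS = GRID_NAMES + ("sex",)

#: Printed default subsample fraction for the tuning grid.
DEFAULT_FRACTION = 0.623


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 200
    mtry: int = 6
    sample_fraction: float = DEFAULT_FRACTION
    min_node: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.mtry <= len(PREDICTORS):
            raise ValueError(f"mtry must be in 1..{len(PREDICTORS)}")
        if not 0.0 < self.sample_fraction < 1.0:
            raise ValueError("sample_fraction must be in (0, 1)")
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")


@dataclass
class FittedForest:
    trees: list[DecisionTreeClassifier]
    inbag: np.ndarray  # (n_trees, n_rows) bool
    feature_names: tuple[str, ...]
    config: ForestConfig
    oob_error: float
    class_prior: float  # fraction of "used" rows in training


@dataclass
class TuningResult:
    grid: list[ForestConfig]
    oob_per_config: list[float]
    chosen: ForestConfig


def design_matrix(table: pd.DataFrame, feature_names=PREDICTORS) -> np.ndarray:
    """Numeric predictor matrix; sex encoded F=0, M=1."""
    missing = [f for f in feature_names if f != "sex" and f not in table.columns]
    if missing:
        raise ValueError(f"table is missing predictors: {missing}")
    cols = []
    for f in feature_names:
        if f == "sex":
            if "sex" not in table.columns:
                raise ValueError("table is missing predictors: ['sex']")
            v = table["sex"]
            if v.dtype == object or str(v.dtype) == "category":
                v = (v == "M").astype(float)
            else:
                v = v.astype(float)
            cols.append(v.to_numpy())
        else:
            cols.append(table[f].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_forest(
    table: pd.DataFrame,
    config: ForestConfig,
    feature_names=PREDICTORS,
) -> FittedForest:
    """Grow the ensemble and measure out-of-bag misclassification.

    Every row must be out-of-bag for at least one tree, otherwise OOB error
    is undefined and fitting fails with advice to lower ``sample_fraction``.
    """
    labels = table["label"].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("table must contain both 'used' and 'available' rows")
    X = design_matrix(table, feature_names)
    y = (labels == "used").astype(int)
    n = X.shape[0]
    n_sub = max(2, int(round(config.sample_fraction * n)))

    rng = np.random.default_rng(config.seed)
    trees: list[DecisionTreeClassifier] = []
    inbag = np.zeros((config.n_trees, n), dtype=bool)
    votes = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for t in range(config.n_trees):
        idx = rng.choice(n, size=n_sub, replace=False)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=min(config.mtry, len(feature_names)),
            min_samples_leaf=config.min_node,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        inbag[t, idx] = True
        oob = ~inbag[t]
        if oob.any():
            votes[oob] += _predict_used(tree, X[oob])
            counts[oob] += 1
    if (counts == 0).any():
        raise ValueError(
            f"{int((counts == 0).sum())} row(s) were never out-of-bag; "
            "lower sample_fraction or raise n_trees"
        )
    oob_pred = (votes / counts) > 0.5
    oob_error = float(np.mean(oob_pred != y.astype(bool)))
    return FittedForest(
        trees=trees,
        inbag=inbag,
        feature_names=tuple(feature_names),
        config=config,
        oob_error=oob_error,
        class_prior=float(y.mean()),
    )


def _predict_used(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    """Per-row 0/1 vote for the 'used' class from one tree."""
    if len(tree.classes_) == 1:
        return np.full(X.shape[0], float(tree.classes_[0]))
    return tree.predict(X).astype(float)


def predict_propensity(fitted: FittedForest, rows: pd.DataFrame) -> np.ndarray:
    """Vote fraction for 'used' across the ensemble, in [0, 1]."""
    X = design_matrix(rows, fitted.feature_names)
    votes = np.zeros(X.shape[0])
    for tree in fitted.trees:
        votes += _predict_used(tree, X)
    return votes / len(fitted.trees)


def default_grid(seed: int = 0) -> list[ForestConfig]:
    """The tuning grid: n_trees x mtry x subsample fraction, one shared seed."""
    grid = []
    for n_trees, mtry, frac in itertools.product(
        (50, 100, 200, 500), (2, 4, 6, 8), (0.4, DEFAULT_FRACTION, 0.8)
    ):
        grid.append(ForestConfig(
            n_trees=n_trees, mtry=mtry, sample_fraction=frac, seed=seed
        ))
    return grid


def tune(
    table: pd.DataFrame,
    grid: list[ForestConfig],
    feature_names=PREDICTORS,
) -> TuningResult:
    """Fit every config, keep the one with the lowest OOB error.

    Ties break toward fewer trees, then smaller mtry, then the subsample
    fraction closest to the 0.623 default.
    """
    if not grid:
        raise ValueError("tuning grid must be non-empty")
    oobs = [fit_forest(table, cfg, feature_names).oob_error for cfg in grid]

    def key(i: int):
        cfg = grid[i]
        return (
            oobs[i],
            cfg.n_trees,
            cfg.mtry,
            abs(cfg.sample_fraction - DEFAULT_FRACTION),
        )

    best = min(range(len(grid)), key=key)
    return TuningResult(grid=list(grid), oob_per_config=oobs, chosen=grid[best])


def permutation_importance(
    fitted: FittedForest,
    table: pd.DataFrame,
    n_reps: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean OOB accuracy decrease when each predictor is permuted.

    For every tree, accuracy on its out-of-bag rows is compared with accuracy
    after shuffling the focal predictor's values within those rows; the
    importance is the mean drop over trees and repetitions.  Returns a frame
    with columns predictor, importance, rank (descending importance).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = design_matrix(table, fitted.feature_names)
    y = (table["label"].to_numpy() == "used").astype(float)
    rng = np.random.default_rng(seed)
    p = len(fitted.feature_names)
    drops = np.zeros(p)
    n_terms = 0
    for t, tree in enumerate(fitted.trees):
        oob = np.flatnonzero(~fitted.inbag[t])
        if oob.size == 0:
            continue
        Xo = X[oob]
        yo = y[oob]
        acc = np.mean(_predict_used(tree, Xo) == yo)
        for _ in range(n_reps):
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xo[rng.permutation(oob.size), j]
                acc_perm = np.mean(_predict_used(tree, Xp) == yo)
                drops[j] += acc - acc_perm
        n_terms += n_reps
    importance = drops / max(n_terms, 1)
    order = np.argsort(-importance, kind="stable")
    ranks = np.empty(p, dtype=int)
    ranks[order] = np.arange(1, p + 1)
    return pd.DataFrame({
        "predictor": fitted.feature_names,
        "importance": importance,
        "rank": ranks,
    })
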