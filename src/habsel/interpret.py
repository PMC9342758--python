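"""Partial dependence, pairwise interaction ranking, and map projection.

Interaction strength of a predictor pair is scored by predicting the model on
an ``n_bins`` x ``n_bins`` grid of the pair's binned values (all other
predictors held at their table means), fitting an additive linear model to
those predictions, and taking its root mean squared residual; a perfectly
additive response leaves zero residual.  Ranked pairs are cut at the largest
drop between consecutive sorted values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import CovariateStack
from .forest_model import FittedForest, design_matrix, predict_propensity

__all__ = [
    "BinningError",
    "PDPCurve",
    "InteractionRanking",
    "PredictionRaster",
    "partial_dependence",
    "interaction_rmse",
    "rank_interactions",
    "project_map",
    "half_rise_point",
]


class BinningError(ValueError):
    """A variable has too few distinct values for the requested binning."""


@dataclass
class PDPCurve:
    predictor: str
    grid: np.ndarray
    dependence: np.ndarray


@dataclass
class InteractionRanking:
    """All pairwise RMSE scores, ranked descending, with max-drop retention."""

    table: pd.DataFrame  # columns: var_a, var_b, rmse, rank, retained

    @property
    def retained_pairs(self) -> list[tuple[str, str]]:
        kept = self.table[self.table["retained"]]
        return list(zip(kept["var_a"], kept["var_b"]))


@dataclass
class PredictionRaster:
    values: np.ndarray  # propensities in [0, 1]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)


def _as_predict_fn(model):
    """Accept a FittedForest or any callable over covariate-row frames."""
    if isinstance(model, FittedForest):
        return lambda rows: predict_propensity(model, rows)
    if callable(model):
        return model
    raise TypeError("model must be a FittedForest or a callable")


def _sex_as_numeric(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    if "sex" in out.columns and out["sex"].dtype == object:
        out["sex"] = (out["sex"] == "M").astype(float)
    return out


def partial_dependence(
    model,
    table: pd.DataFrame,
    predictor: str,
    n_grid: int = 20,
) -> PDPCurve:
    """Average prediction as a function of one predictor.

    The grid holds ``n_grid`` equally spaced quantiles between the 1st and
    99th percentiles of the predictor in ``table``; at each grid value the
    predictor column is overwritten for every row and predictions averaged.
    """
    if n_grid < 5:
        raise ValueError("n_grid must be >= 5")
    predict = _as_predict_fn(model)
    data = _sex_as_numeric(table)
    if predictor not in data.columns:
        raise ValueError(f"unknown predictor {predictor!r}")
    col = data[predictor].to_numpy(dtype=float)
    qs = np.linspace(0.01, 0.99, n_grid)
    grid = np.unique(np.quantile(col, qs))
    if grid.size == 1:
        warnings.warn(
            f"predictor {predictor!r} is constant; single-point curve",
            RuntimeWarning,
            stacklevel=2,
        )
    dependence = np.empty(grid.size)
    for i, g in enumerate(grid):
        rows = data.copy()
        rows[predictor] = g
        dependence[i] = float(np.mean(predict(rows)))
    return PDPCurve(predictor=predictor, grid=grid, dependence=dependence)


def _bin_midpoints(
    col: np.ndarray, n_bins: int, discrete_ok: bool = False
) -> np.ndarray:
    """Equal-frequency bin representatives: midpoints of bin-edge quantiles.

    With ``discrete_ok`` a variable with fewer than ``n_bins`` distinct
    values (e.g. the binary sex indicator, or a constant column) is
    represented by its distinct values instead of erroring.
    """
    uniq = np.unique(col)
    if uniq.size < n_bins:
        if discrete_ok and uniq.size >= 1:
            return uniq
        raise BinningError(
            f"variable has fewer than {n_bins} distinct values"
        )
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1))
    return (edges[:-1] + edges[1:]) / 2.0


def interaction_design(
    table: pd.DataFrame,
    pair: tuple[str, str],
    n_bins: int = 10,
    feature_names=None,
    discrete_ok: bool = False,
) -> pd.DataFrame:
    """The n_bins^2 evaluation rows for one pair, others fixed at means."""
    a, b = pair
    if a == b:
        raise ValueError("pair must name two distinct predictors")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    data = _sex_as_numeric(table)
    if feature_names is None:
        feature_names = [c for c in data.columns if np.issubdtype(
            np.asarray(data[c]).dtype, np.number)]
    va = _bin_midpoints(data[a].to_numpy(dtype=float), n_bins, discrete_ok)
    vb = _bin_midpoints(data[b].to_numpy(dtype=float), n_bins, discrete_ok)
    means = {f: float(data[f].to_numpy(dtype=float).mean()) for f in feature_names}
    rows = []
    for x in va:
        for yv in vb:
            r = dict(means)
            r[a] = float(x)
            r[b] = float(yv)
            rows.append(r)
    return pd.DataFrame(rows)


def interaction_rmse(
    model,
    table: pd.DataFrame,
    pair: tuple[str, str],
    n_bins: int = 10,
    feature_names=None,
    discrete_ok: bool = False,
) -> float:
    """Root mean squared residual of an additive fit to the pair's grid.

    Predictions on the bin-combination grid are regressed on
    ``1 + v_a + v_b`` (bin values as continuous regressors, no product
    term); the returned value is the RMSE of that fit.
    """
    predict = _as_predict_fn(model)
    design = interaction_design(table, pair, n_bins, feature_names, discrete_ok)
    preds = np.asarray(predict(design), dtype=float)
    a, b = pair
    Xr = np.column_stack([
        np.ones(len(design)),
        design[a].to_numpy(),
        design[b].to_numpy(),
    ])
    beta, *_ = np.linalg.lstsq(Xr, preds, rcond=None)
    resid = preds - Xr @ beta
    return float(np.sqrt(np.mean(resid**2)))


def rank_interactions(
    model,
    table: pd.DataFrame,
    feature_names=None,
    n_bins: int = 10,
) -> InteractionRanking:
    """Score all predictor pairs, sort descending, cut at the max RMSE drop.

    Pairs above the largest gap between consecutive sorted RMSEs are
    retained; if every gap is zero only the top pair is retained.
    """
    if feature_names is None:
        if isinstance(model, FittedForest):
            feature_names = list(model.feature_names)
        else:
            raise ValueError("feature_names required for a callable model")
    if len(feature_names) < 2:
        raise ValueError("need at least 2 predictors")
    records = []
    for a, b in itertools.combinations(feature_names, 2):
        rmse = interaction_rmse(
            model, table, (a, b), n_bins, feature_names, discrete_ok=True
        )
        records.append({"var_a": a, "var_b": b, "rmse": rmse})
    df = pd.DataFrame.from_records(records)
    df = df.sort_values("rmse", ascending=False, kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    gaps = -np.diff(df["rmse"].to_numpy())
    cut = int(np.argmax(gaps)) + 1 if len(gaps) else 1
    df["retained"] = df["rank"] <= cut
    return InteractionRanking(table=df)


def project_map(fitted: FittedForest, stack: CovariateStack) -> PredictionRaster:
    """Propensity raster: per-cell prediction averaged over the two sexes."""
    non_sex = tuple(f for f in fitted.feature_names if f != "sex")
    if set(non_sex) != set(stack.grids):
        raise ValueError(
            "stack bands do not match the model's non-sex predictors: "
            f"{sorted(set(non_sex) ^ set(stack.grids))}"
        )
    nr, nc = stack.shape
    flat = pd.DataFrame({n: g.ravel() for n, g in stack.grids.items()})
    out = np.zeros(nr * nc)
    chunk = 200_000
    for start in range(0, len(flat), chunk):
        block = flat.iloc[start:start + chunk]
        acc = np.zeros(len(block))
        for sex_val in (0.0, 1.0):
            rows = block.assign(sex=sex_val)
            acc += predict_propensity(fitted, rows)
        out[start:start + len(block)] = acc / 2.0
    return PredictionRaster(
        values=out.reshape(nr, nc), cell_size=stack.cell_size, origin=stack.origin
    )


def half_rise_point(curve: PDPCurve, plateau_frac: float = 0.25) -> float:
    """First grid value where dependence exceeds midway between its minimum
    and the plateau mean (mean over the last ``plateau_frac`` of the grid)."""
    dep = curve.dependence
    n_tail = max(1, int(round(plateau_frac * dep.size)))
    plateau = float(dep[-n_tail:].mean())
    mid = (float(dep.min()) + plateau) / 2.0
    above = np.flatnonzero(dep > mid)
    if above.size == 0:
        return float(curve.grid[-1])
    return float(curve.grid[above[0]])
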