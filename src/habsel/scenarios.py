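"""Benchmark scenarios with known ground truth.

Each builder assembles a landscape, covariates, telemetry from a known
selection function, and a use-availability table, sized to run in seconds on
one CPU.  They are used by the recovery tests (threshold location, product
interaction, cross-validated AUC) and by the acceptance report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .covariates import CovariateStack, EvennessParams, build_stack
from .design import build_table
from .landscape_sim import LandscapeConfig, generate_landscape, generate_roads
from .telemetry_sim import (
    Individual,
    TrueRSF,
    sample_used_points,
)

__all__ = [
    "Scenario",
    "make_stack",
    "threshold_recovery_scenario",
    "interaction_recovery_scenario",
    "multi_individual_scenario",
    "shuffle_labels_within_individuals",
]


@dataclass
class Scenario:
    stack: CovariateStack
    rsf: TrueRSF
    table: pd.DataFrame


def make_stack(
    n_rows: int = 200,
    n_cols: int = 200,
    smoothing_length: float = 500.0,
    evenness_radius: float = 400.0,
    seed: int = 0,
) -> CovariateStack:
    """Landscape + roads + covariates in one call."""
    cfg = LandscapeConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=30.0,
        smoothing_length=smoothing_length,
        n_major_roads=1,
        n_minor_roads=2,
        seed=seed,
    )
    class_map = generate_landscape(cfg)
    roads = generate_roads(cfg, seed=seed + 1)
    return build_stack(class_map, roads, EvennessParams(window_radius=evenness_radius))


def _single_individual_table(
    stack: CovariateStack,
    rsf: TrueRSF,
    n_used: int,
    ratio: int,
    seed: int,
    radius_frac: float = 0.42,
) -> pd.DataFrame:
    """Used + available rows for one individual centered on the stack."""
    x0, y0, x1, y1 = stack.extent
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    radius = radius_frac * min(x1 - x0, y1 - y0)
    ind = Individual(
        id="B01", sex="F", center=(cx, cy),
        availability_radius=radius, n_points=n_used,
    )
    used = sample_used_points(ind, stack, rsf, seed=seed)
    domain = Point(cx, cy).buffer(radius, quad_segs=64)
    return build_table(used, stack, domain, ratio=ratio,
                       scale="study_area", seed=seed + 1)


def threshold_recovery_scenario(
    seed: int,
    cutoff: float = 1000.0,
    n_used: int = 2000,
    ratio: int = 3,
) -> Scenario:
    """Hard avoidance of agriculture within ``cutoff`` meters.

    The true weight is 0 where dist_agriculture < cutoff and 1 elsewhere, so
    a fitted model's partial dependence on dist_agriculture should rise at
    the cutoff.  Patches are smoothed enough that distances well beyond the
    cutoff exist inside the availability disc.
    """
    stack = make_stack(smoothing_length=500.0, seed=seed)
    rsf = TrueRSF(rules=[{"covariate": "dist_agriculture", "min": cutoff}])
    table = _single_individual_table(stack, rsf, n_used, ratio, seed=seed + 10)
    return Scenario(stack=stack, rsf=rsf, table=table)


def interaction_recovery_scenario(
    seed: int,
    pair: tuple[str, str] = ("dist_forest_signed", "dist_major_road"),
    strength: float = 2.0,
    n_used: int = 1500,
    ratio: int = 3,
) -> Scenario:
    """True selection driven purely by a product interaction.

    The interaction coefficient is scaled by the reciprocal covariate SDs
    over the raster so ``strength`` is the effect per SD x SD unit.
    """
    stack = make_stack(smoothing_length=400.0, seed=seed)
    a, b = pair
    sd_a = float(stack.grids[a].std())
    sd_b = float(stack.grids[b].std())
    mu_a = float(stack.grids[a].mean())
    mu_b = float(stack.grids[b].mean())
    # centered product: exp(s * (za - mua)(zb - mub) / (sda*sdb))
    coef = strength / (sd_a * sd_b)
    rsf = TrueRSF(
        coefficients={a: -coef * mu_b, b: -coef * mu_a},
        interactions={(a, b): coef},
        intercept=coef * mu_a * mu_b,
    )
    table = _single_individual_table(stack, rsf, n_used, ratio, seed=seed + 10)
    return Scenario(stack=stack, rsf=rsf, table=table)


def multi_individual_scenario(
    seed: int,
    n_individuals: int = 27,
    sex_split: tuple[int, int] = (14, 13),
    n_points_mean: float = 60.0,
    ratio: int = 2,
    strength: float = 1.5,
    n_rows: int = 200,
    n_cols: int = 200,
) -> Scenario:
    """Many individuals under a shared strongly-selective log-linear truth.

    Coefficients put ``strength`` SD-units of effect on signed forest
    distance (negative: selection into forest) and agriculture distance
    (positive: avoidance of agriculture edges).
    """
    stack = make_stack(n_rows=n_rows, n_cols=n_cols, smoothing_length=400.0,
                       seed=seed)
    sd_f = float(stack.grids["dist_forest_signed"].std())
    sd_a = float(stack.grids["dist_agriculture"].std())
    rsf = TrueRSF(coefficients={
        "dist_forest_signed": -strength / sd_f,
        "dist_agriculture": strength / sd_a,
    })
    x0, y0, x1, y1 = stack.extent
    radius = 0.2 * min(x1 - x0, y1 - y0)
    rng = np.random.default_rng(seed + 5)
    sexes = ["M"] * sex_split[0] + ["F"] * sex_split[1]
    assert len(sexes) == n_individuals
    frames = []
    domains = {}
    for i, sex in enumerate(sexes):
        cx = rng.uniform(x0 + radius, x1 - radius)
        cy = rng.uniform(y0 + radius, y1 - radius)
        npts = max(20, int(round(rng.normal(n_points_mean, n_points_mean / 6))))
        ind = Individual(id=f"B{i + 1:02d}", sex=sex, center=(cx, cy),
                         availability_radius=radius, n_points=npts)
        frames.append(sample_used_points(ind, stack, rsf, seed=seed + 31 * (i + 1)))
        domains[ind.id] = Point(cx, cy).buffer(radius, quad_segs=64)
    used = pd.concat(frames, ignore_index=True)
    table = build_table(used, stack, domains, ratio=ratio,
                        scale="study_area", seed=seed + 7)
    return Scenario(stack=stack, rsf=rsf, table=table)


def shuffle_labels_within_individuals(
    table: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Permute used/available labels within each individual (null model)."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["label"] = out.groupby("id")["label"].transform(
        lambda s: s.to_numpy()[rng.permutation(len(s))]
    )
    return out
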