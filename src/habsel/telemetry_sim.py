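"""Telemetry simulation from a known true selection function.

Individuals get a center and a circular availability disc; used points are
drawn by rejection sampling proportional to a configurable nonnegative weight
function of the covariates, then perturbed by isotropic location error.  The
ground truth is therefore fully known and recoverable by the downstream
model, which is what makes every later stage testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack, extract
from .landscape_sim import HabitatClassMap
from .ranges import radius_from_area

__all__ = [
    "IllConditionedRSFError",
    "ExtentError",
    "Individual",
    "TrueRSF",
    "ErrorModel",
    "simulate_individuals",
    "sample_used_points",
    "apply_location_error",
    "simulate_telemetry",
]

#: mean displacement of a Rayleigh(sigma) variable is sigma * sqrt(pi/2)
_RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)


class IllConditionedRSFError(RuntimeError):
    """Rejection sampling acceptance rate collapsed below threshold."""


class ExtentError(ValueError):
    """Map extent too small for the requested geometry."""


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # "M" or "F"
    center: tuple[float, float]
    availability_radius: float
    n_points: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.availability_radius <= 0:
            raise ValueError("availability_radius must be > 0")


@dataclass
class TrueRSF:
    """Nonnegative selection weight over covariate rows.

    ``w(z) = exp(intercept + sum_i c_i z_i + sum_ab c_ab z_a z_b)`` times a
    0/1 indicator for every threshold rule.  A rule is a dict with keys
    ``covariate`` and at least one of ``min``/``max``; rows violating any
    rule get weight 0.  ``sex_offsets`` adds a per-sex intercept shift so
    tests can probe sex effects.
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    rules: list[dict] = field(default_factory=list)
    intercept: float = 0.0
    sex_offsets: dict[str, float] = field(default_factory=dict)

    def covariate_names(self) -> set[str]:
        names = set(self.coefficients)
        for a, b in self.interactions:
            names.update((a, b))
        for rule in self.rules:
            names.add(rule["covariate"])
        return names

    def weight(self, rows: pd.DataFrame, sex: str | None = None) -> np.ndarray:
        missing = self.covariate_names() - set(rows.columns)
        if missing:
            raise KeyError(f"RSF references covariates absent from stack: {missing}")
        lin = np.full(len(rows), self.intercept, dtype=float)
        if sex is not None and self.sex_offsets:
            lin += self.sex_offsets.get(sex, 0.0)
        for name, coef in self.coefficients.items():
            lin += coef * rows[name].to_numpy()
        for (a, b), coef in self.interactions.items():
            lin += coef * rows[a].to_numpy() * rows[b].to_numpy()
        w = np.exp(lin)
        for rule in self.rules:
            v = rows[rule["covariate"]].to_numpy()
            ok = np.ones(len(rows), dtype=bool)
            if "min" in rule:
                ok &= v >= rule["min"]
            if "max" in rule:
                ok &= v <= rule["max"]
            w = np.where(ok, w, 0.0)
        return w


@dataclass(frozen=True)
class ErrorModel:
    """Isotropic location error parameterized by mean displacement (m)."""

    sd: float = 94.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("error magnitude must be >= 0")

    @property
    def component_sd(self) -> float:
        """Per-axis normal sd giving mean displacement equal to ``sd``."""
        return self.sd / _RAYLEIGH_MEAN_FACTOR


def simulate_individuals(
    n: int,
    sex_split: tuple[int, int],
    class_map: HabitatClassMap,
    mean_hr_area: float,
    seed: int,
    n_points_mean: float = 258.0,
    n_points_sd: float = 36.0,
    n_points_min: int = 30,
    availability_radius: float | None = None,
) -> list[Individual]:
    """Draw individuals with uniform centers and normal point counts.

    ``sex_split`` is (n_males, n_females) and must sum to ``n``.  Centers are
    uniform over the map interior inset by the availability radius, which
    defaults to the radius of a circle of ``mean_hr_area`` (m^2).
    """
    if n != sum(sex_split):
        raise ValueError("n must equal sum(sex_split)")
    if mean_hr_area <= 0:
        raise ValueError("mean_hr_area must be > 0")
    radius = (
        availability_radius
        if availability_radius is not None
        else radius_from_area(mean_hr_area)
    )
    x0, y0, x1, y1 = class_map.extent
    if x1 - x0 <= 2 * radius or y1 - y0 <= 2 * radius:
        raise ExtentError(
            f"map extent {x1 - x0:.0f} x {y1 - y0:.0f} m cannot fit a "
            f"{radius:.0f} m availability margin"
        )
    rng = np.random.default_rng(seed)
    sexes = ["M"] * sex_split[0] + ["F"] * sex_split[1]
    out = []
    for i, sex in enumerate(sexes):
        cx = rng.uniform(x0 + radius, x1 - radius)
        cy = rng.uniform(y0 + radius, y1 - radius)
        npts = max(n_points_min, int(round(rng.normal(n_points_mean, n_points_sd))))
        out.append(
            Individual(
                id=f"B{i + 1:02d}",
                sex=sex,
                center=(cx, cy),
                availability_radius=radius,
                n_points=npts,
            )
        )
    return out


def _disc_weight_max(
    ind: Individual, stack: CovariateStack, rsf: TrueRSF
) -> float:
    """Exact max of w over the availability disc (covariates are cellwise)."""
    xs = np.arange(stack.shape[1])
    ys = np.arange(stack.shape[0])
    x0, y0 = stack.origin
    cx = x0 + (xs + 0.5) * stack.cell_size
    cy = y0 + (ys + 0.5) * stack.cell_size
    dx2 = (cx - ind.center[0]) ** 2
    dy2 = (cy - ind.center[1]) ** 2
    inside = dy2[:, None] + dx2[None, :] <= ind.availability_radius**2
    rows, cols = np.nonzero(inside)
    if rows.size == 0:
        raise ExtentError("availability disc covers no cell centers")
    z = pd.DataFrame({n: g[rows, cols] for n, g in stack.grids.items()})
    return float(rsf.weight(z, sex=ind.sex).max())


def sample_used_points(
    ind: Individual,
    stack: CovariateStack,
    rsf: TrueRSF,
    seed: int,
    min_acceptance: float = 1e-4,
) -> pd.DataFrame:
    """Rejection-sample ``ind.n_points`` used locations from the disc.

    Proposals are uniform over the availability disc intersected with the
    raster extent; acceptance probability is w(z)/w_max with w_max taken over
    disc cells (exact, since covariates are cellwise constant).
    """
    w_max = _disc_weight_max(ind, stack, rsf)
    if w_max <= 0:
        raise IllConditionedRSFError("RSF weight is zero over the whole disc")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = stack.extent
    accepted_x: list[np.ndarray] = []
    accepted_y: list[np.ndarray] = []
    n_have = 0
    n_proposed = 0
    batch = max(4 * ind.n_points, 256)
    while n_have < ind.n_points:
        r = ind.availability_radius * np.sqrt(rng.uniform(size=batch))
        theta = rng.uniform(0, 2 * math.pi, size=batch)
        px = ind.center[0] + r * np.cos(theta)
        py = ind.center[1] + r * np.sin(theta)
        u = rng.uniform(size=batch)
        n_proposed += batch
        in_extent = (px >= x0) & (px <= x1) & (py >= y0) & (py <= y1)
        px, py, u = px[in_extent], py[in_extent], u[in_extent]
        if px.size:
            z = extract(stack, np.column_stack([px, py]))
            keep = u < rsf.weight(z, sex=ind.sex) / w_max
            accepted_x.append(px[keep])
            accepted_y.append(py[keep])
            n_have += int(keep.sum())
        if n_proposed >= 10_000 and n_have / n_proposed < min_acceptance:
            raise IllConditionedRSFError(
                f"acceptance rate {n_have / n_proposed:.2e} below "
                f"{min_acceptance:.0e} for individual {ind.id}"
            )
    xs = np.concatenate(accepted_x)[: ind.n_points]
    ys = np.concatenate(accepted_y)[: ind.n_points]
    return pd.DataFrame(
        {"id": ind.id, "sex": ind.sex, "x": xs, "y": ys}
    )


def apply_location_error(
    records: pd.DataFrame,
    err: ErrorModel,
    extent: tuple[float, float, float, float],
    seed: int,
    max_tries: int = 100,
) -> pd.DataFrame:
    """Displace each point by isotropic bivariate normal noise.

    The per-axis sd is chosen so the mean displacement length equals
    ``err.sd``.  Displacements landing outside ``extent`` are redrawn, up to
    ``max_tries`` per point.
    """
    out = records.copy()
    if err.sd == 0 or len(records) == 0:
        return out
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = extent
    sigma = err.component_sd
    x = out["x"].to_numpy(dtype=float, copy=True)
    y = out["y"].to_numpy(dtype=float, copy=True)
    pending = np.arange(x.size)
    for _ in range(max_tries):
        dx = rng.normal(0, sigma, size=pending.size)
        dy = rng.normal(0, sigma, size=pending.size)
        nx, ny = x[pending] + dx, y[pending] + dy
        ok = (nx >= x0) & (nx <= x1) & (ny >= y0) & (ny <= y1)
        x[pending[ok]] = nx[ok]
        y[pending[ok]] = ny[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise ExtentError(
            f"{pending.size} point(s) could not be displaced inside the "
            f"extent after {max_tries} tries"
        )
    out["x"] = x
    out["y"] = y
    return out


def simulate_telemetry(
    individuals: list[Individual],
    stack: CovariateStack,
    rsf: TrueRSF,
    err: ErrorModel,
    seed: int,
) -> pd.DataFrame:
    """Used points for every individual, with location error applied."""
    frames = []
    for i, ind in enumerate(individuals):
        pts = sample_used_points(ind, stack, rsf, seed=seed + 1000 * (i + 1))
        frames.append(pts)
    used = pd.concat(frames, ignore_index=True)
    return apply_location_error(used, err, stack.extent, seed=seed + 7)
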