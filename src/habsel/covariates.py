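"""Distance and evenness covariate grids, and point extraction.

Builds the eight-predictor raster space: five habitat-class distances (forest
signed, the rest nonnegative), two road-class distances, and a moving-window
habitat evenness index.  All distances are Euclidean, measured between cell
centers (roads: cell center to vector geometry), in meters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, signal

from .landscape_sim import CLASS_NAMES, N_CLASSES, HabitatClassMap, RoadNetwork

__all__ = [
    "GRID_NAMES",
    "AbsentClassError",
    "DegenerateMapError",
    "PointOutsideRasterError",
    "EvennessParams",
    "CovariateStack",
    "distance_to_class",
    "signed_forest_distance",
    "distance_to_roads",
    "evenness",
    "evenness_index",
    "build_stack",
    "extract",
]

log = logging.getLogger(__name__)

#: Canonical band order of a covariate stack.
GRID_NAMES = (
    "dist_forest_signed",
    "dist_agriculture",
    "dist_grassland",
    "dist_water",
    "dist_developed",
    "dist_major_road",
    "dist_minor_road",
    "evenness",
)


class AbsentClassError(ValueError):
    """Distance to a class that does not occur in the map is undefined."""


class DegenerateMapError(ValueError):
    """Signed forest distance needs both forest and non-forest cells."""


class PointOutsideRasterError(ValueError):
    def __init__(self, index: int, xy: tuple[float, float]):
        self.index = index
        super().__init__(f"point {index} at {xy} lies outside the raster extent")


@dataclass(frozen=True)
class EvennessParams:
    """Moving-window parameters for the evenness grid."""

    window_radius: float = 6555.0  # meters; desk-scale runs override this
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.window_radius <= 0:
            raise ValueError("window_radius must be > 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class CovariateStack:
    """Named real-valued grids aligned to a source :class:`HabitatClassMap`."""

    grids: dict[str, np.ndarray]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        shapes = {g.shape for g in self.grids.values()}
        if len(shapes) != 1:
            raise ValueError("all grids must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.grids)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        nr, nc = self.shape
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)


def distance_to_class(class_map: HabitatClassMap, class_name: str) -> np.ndarray:
    """Euclidean distance (m) from each cell center to the nearest center of
    a cell of ``class_name``; exact via the Euclidean distance transform."""
    code = CLASS_NAMES.index(class_name)
    mask = class_map.classes == code
    if not mask.any():
        raise AbsentClassError(
            f"class {class_name!r} absent from map; distance undefined"
        )
    return ndimage.distance_transform_edt(~mask, sampling=class_map.cell_size)


def signed_forest_distance(class_map: HabitatClassMap) -> np.ndarray:
    """Distance to forest, negated inside forest.

    Non-forest cells get +distance to the nearest forest cell center; forest
    cells get -distance to the nearest non-forest cell center.
    """
    forest = class_map.classes == CLASS_NAMES.index("forest")
    if not forest.any() or forest.all():
        raise DegenerateMapError(
            "signed forest distance needs both forest and non-forest cells"
        )
    d_to_forest = ndimage.distance_transform_edt(
        ~forest, sampling=class_map.cell_size
    )
    d_to_nonforest = ndimage.distance_transform_edt(
        forest, sampling=class_map.cell_size
    )
    return np.where(forest, -d_to_nonforest, d_to_forest)


def distance_to_roads(
    frame: HabitatClassMap | CovariateStack,
    roads: RoadNetwork,
    road_class: str,
) -> np.ndarray:
    """Distance (m) from each cell center to the nearest polyline of the class.

    If no roads of the class exist, every cell receives a sentinel equal to
    the map diagonal length (logged) so the covariate stays well defined.
    """
    if road_class not in ("major", "minor"):
        raise ValueError(f"unknown road class {road_class!r}")
    nr, nc = frame.shape if isinstance(frame, CovariateStack) else frame.classes.shape
    x0, y0 = frame.origin
    cell = frame.cell_size
    lines = roads.lines(road_class)
    if not lines:
        sentinel = math.hypot(nc * cell, nr * cell)
        log.warning(
            "no %s roads present; filling distance grid with sentinel %.1f m",
            road_class, sentinel,
        )
        return np.full((nr, nc), sentinel)
    xs = x0 + (np.arange(nc) + 0.5) * cell
    ys = y0 + (np.arange(nr) + 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(xx.ravel(), yy.ravel())
    geom = shapely.union_all(lines)
    return shapely.distance(pts, geom).reshape(nr, nc)


def evenness_index(proportions, n_classes: int = N_CLASSES) -> float:
    """Shannon evenness -sum(P_i ln P_i)/ln(n) with 0*ln(0) := 0."""
    p = np.asarray(proportions, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return float(-terms.sum() / math.log(n_classes)) + 0.0


def _circular_footprint(radius_cells: float) -> np.ndarray:
    r_int = int(math.floor(radius_cells))
    offs = np.arange(-r_int, r_int + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (dy * dy + dx * dx) <= radius_cells * radius_cells


def evenness(class_map: HabitatClassMap, params: EvennessParams) -> np.ndarray:
    """Moving-window Shannon evenness in [0, 1].

    The window at a focal cell comprises all cells whose centers fall within
    ``window_radius`` of the focal center; windows are clipped at map edges
    (proportions over in-map cells only).  ``n`` in the index is fixed at the
    legend size, not the count of classes present in the window.
    """
    if params.window_radius < class_map.cell_size:
        raise ValueError("window_radius must be >= cell_size")
    kernel = _circular_footprint(params.window_radius / class_map.cell_size)
    nr, nc = class_map.classes.shape
    # FFT convolution for big kernels; counts are integers, so round to
    # recover them exactly.
    use_fft = kernel.size * nr * nc > 2e7
    counts = np.empty((N_CLASSES, nr, nc))
    ones = np.ones((nr, nc))
    if use_fft:
        kern = kernel.astype(float)
        total = np.rint(signal.fftconvolve(ones, kern, mode="same"))
        for k in range(N_CLASSES):
            ind = (class_map.classes == k).astype(float)
            counts[k] = np.rint(signal.fftconvolve(ind, kern, mode="same"))
    else:
        total = ndimage.convolve(ones, kernel.astype(float), mode="constant", cval=0.0)
        for k in range(N_CLASSES):
            ind = (class_map.classes == k).astype(float)
            counts[k] = ndimage.convolve(ind, kernel.astype(float), mode="constant", cval=0.0)
    p = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    he = -terms.sum(axis=0) / math.log(params.n_classes)
    return np.clip(he, 0.0, 1.0)


def build_stack(
    class_map: HabitatClassMap,
    roads: RoadNetwork,
    evenness_params: EvennessParams,
) -> CovariateStack:
    """Assemble the full eight-band covariate stack from a map and roads."""
    grids = {"dist_forest_signed": signed_forest_distance(class_map)}
    for name in CLASS_NAMES[1:]:
        grids[f"dist_{name}"] = distance_to_class(class_map, name)
    grids["dist_major_road"] = distance_to_roads(class_map, roads, "major")
    grids["dist_minor_road"] = distance_to_roads(class_map, roads, "minor")
    grids["evenness"] = evenness(class_map, evenness_params)
    grids = {name: grids[name] for name in GRID_NAMES}
    return CovariateStack(
        grids=grids, cell_size=class_map.cell_size, origin=class_map.origin
    )


def cell_index(
    stack: CovariateStack, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map coordinates to (row, col); raises for out-of-extent points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x0, y0, x1, y1 = stack.extent
    outside = (x < x0) | (x > x1) | (y < y0) | (y > y1)
    if outside.any():
        i = int(np.flatnonzero(outside)[0])
        raise PointOutsideRasterError(i, (float(x[i]), float(y[i])))
    nr, nc = stack.shape
    col = np.clip(np.floor((x - x0) / stack.cell_size).astype(int), 0, nc - 1)
    row = np.clip(np.floor((y - y0) / stack.cell_size).astype(int), 0, nr - 1)
    return row, col


def extract(stack: CovariateStack, points) -> pd.DataFrame:
    """Read every grid at the cell containing each (x, y) point.

    Points exactly on the outer boundary are assigned to the nearest edge
    cell.  Returns one row per point, one column per grid, in band order.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col = cell_index(stack, pts[:, 0], pts[:, 1])
    return pd.DataFrame(
        {name: grid[row, col] for name, grid in stack.grids.items()}
    )
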