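"""Synthetic categorical landscapes and road networks.

A landscape is a rectangular grid of habitat class labels on a projected-meters
lattice.  Patches are produced by smoothing one standard-normal noise field per
class and labelling each cell by the weighted argmax across fields; the
per-class weights are calibrated iteratively so the realized class composition
matches a target within a stated tolerance.

Coordinate convention (shared by every module in this package): projected
meters, origin at the map lower-left corner, row 0 at the bottom, 0-based
indices, and the center of cell ``(row, col)`` at
``origin + (col + 0.5, row + 0.5) * cell_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString

__all__ = [
    "CLASS_NAMES",
    "CalibrationError",
    "LandscapeConfig",
    "HabitatClassMap",
    "RoadNetwork",
    "generate_landscape",
    "generate_roads",
    "composition",
]

#: Fixed legend: integer code == index into this tuple.
CLASS_NAMES = ("forest", "agriculture", "grassland", "water", "developed")
N_CLASSES = len(CLASS_NAMES)


class CalibrationError(RuntimeError):
    """Raised when composition calibration fails to converge."""


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters controlling one synthetic landscape realization."""

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    target_composition: tuple[float, ...] = (0.54, 0.35, 0.04, 0.02, 0.05)
    smoothing_length: float = 300.0
    n_major_roads: int = 1
    n_minor_roads: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.target_composition, dtype=float)
        if comp.shape != (N_CLASSES,):
            raise ValueError(f"target_composition must have {N_CLASSES} entries")
        if (comp < 0).any():
            raise ValueError("target_composition entries must be nonnegative")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("target_composition must sum to 1 within 1e-9")
        if self.n_rows < 10 or self.n_cols < 10:
            raise ValueError("n_rows and n_cols must be >= 10")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_major_roads < 0 or self.n_minor_roads < 0:
            raise ValueError("road counts must be >= 0")


@dataclass
class HabitatClassMap:
    """Grid of habitat class codes (0..4, see :data:`CLASS_NAMES`)."""

    classes: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2 or self.classes.size == 0:
            raise ValueError("classes must be a non-empty 2-D array")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("classes must hold integer class codes")
        if self.classes.min() < 0 or self.classes.max() >= N_CLASSES:
            raise ValueError(f"class codes must lie in 0..{N_CLASSES - 1}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the map footprint."""
        x0, y0 = self.origin
        nr, nc = self.classes.shape
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (row + 0.5) * self.cell_size)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate vectors of all column (x) and row (y) centers."""
        x0, y0 = self.origin
        nr, nc = self.classes.shape
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nr) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class RoadNetwork:
    """Polylines in map coordinates, each tagged 'major' or 'minor'."""

    roads: list[tuple[LineString, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for line, cls in self.roads:
            if cls not in ("major", "minor"):
                raise ValueError(f"unknown road class {cls!r}")
            if len(line.coords) < 2:
                raise ValueError("road polyline must have >= 2 vertices")

    def lines(self, road_class: str) -> list[LineString]:
        return [g for g, c in self.roads if c == road_class]


def composition(class_map: HabitatClassMap) -> np.ndarray:
    """Realized proportion of each class, in legend order."""
    counts = np.bincount(class_map.classes.ravel(), minlength=N_CLASSES)
    return counts / class_map.classes.size


def generate_landscape(
    config: LandscapeConfig,
    tolerance: float = 0.01,
    max_iter: int = 200,
) -> HabitatClassMap:
    """Generate a class map matching ``config.target_composition``.

    One smoothed standard-normal field per class; a cell takes the class with
    the largest ``weight + field`` value.  Weights start at 0 and are adjusted
    proportionally until every realized class proportion is within
    ``tolerance`` of its target.  Classes with a zero target are excluded
    outright.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    target = np.asarray(config.target_composition, dtype=float)
    nr, nc = config.n_rows, config.n_cols
    sigma = config.smoothing_length / config.cell_size

    fields = np.empty((N_CLASSES, nr, nc))
    for k in range(N_CLASSES):
        f = rng.standard_normal((nr, nc))
        if sigma > 0:
            f = gaussian_filter(f, sigma=sigma, mode="reflect")
        sd = f.std()
        fields[k] = (f - f.mean()) / (sd if sd > 0 else 1.0)

    active = target > 0
    weights = np.zeros(N_CLASSES)
    weights[~active] = -np.inf

    # damped log-ratio correction: relative errors keep rare classes stable
    step = 0.5
    floor = 1.0 / labels_size if (labels_size := nr * nc) else 1.0
    best_err = np.inf
    best_labels = None
    realized = target
    for _ in range(max_iter):
        labels = np.argmax(weights[:, None, None] + fields, axis=0)
        realized = np.bincount(labels.ravel(), minlength=N_CLASSES) / labels.size
        err = np.abs(realized - target).max()
        if err < best_err:
            best_err = err
            best_labels = labels
        else:
            step = max(step * 0.7, 0.02)
        if best_err <= tolerance * 0.8:
            break
        ratio = np.log(target[active] / np.maximum(realized[active], floor))
        weights[active] += step * np.clip(ratio, -2.0, 2.0)
        weights[active] -= weights[active].mean()  # fix the gauge
    if best_err > tolerance:
        worst = int(np.argmax(np.abs(realized - target)))
        raise CalibrationError(
            f"composition calibration failed after {max_iter} iterations; "
            f"worst class {CLASS_NAMES[worst]!r}: realized "
            f"{realized[worst]:.4f} vs target {target[worst]:.4f}"
        )
    labels = best_labels

    return HabitatClassMap(
        classes=labels.astype(np.int8), cell_size=config.cell_size
    )


def generate_roads(config: LandscapeConfig, seed: int) -> RoadNetwork:
    """Random polylines crossing the map extent, per road class.

    Each road joins a random point on one edge of the extent to a random point
    on the opposite edge, with three jittered interior vertices, so every road
    fully crosses the map.  Deterministic for (config, seed).
    """
    rng = np.random.default_rng(seed)
    width = config.n_cols * config.cell_size
    height = config.n_rows * config.cell_size
    roads: list[tuple[LineString, str]] = []

    def one_road() -> LineString:
        if rng.random() < 0.5:  # west-east
            p0 = (0.0, rng.uniform(0, height))
            p1 = (width, rng.uniform(0, height))
            jitter_axis = 1
            jitter_scale = height
        else:  # south-north
            p0 = (rng.uniform(0, width), 0.0)
            p1 = (rng.uniform(0, width), height)
            jitter_axis = 0
            jitter_scale = width
        ts = np.sort(rng.uniform(0.2, 0.8, size=3))
        pts = [p0]
        for t in ts:
            p = [p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1])]
            p[jitter_axis] = float(
                np.clip(p[jitter_axis] + rng.normal(0, 0.05 * jitter_scale),
                        0, jitter_scale)
            )
            pts.append(tuple(p))
        pts.append(p1)
        return LineString(pts)

    for _ in range(config.n_major_roads):
        roads.append((one_road(), "major"))
    for _ in range(config.n_minor_roads):
        roads.append((one_road(), "minor"))
    return RoadNetwork(roads=roads)
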