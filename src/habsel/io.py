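"""Plain-text artifact I/O: ESRI ASCII grids, GeoJSON, CSV, YAML.

Rasters use the ESRI ASCII grid format (``.asc``) with a JSON sidecar for
legends/band metadata instead of GeoTIFF, keeping every artifact text-based
and diffable.  Vector data is GeoJSON written via shapely's mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import LineString, mapping, shape

from .covariates import CovariateStack, GRID_NAMES
from .landscape_sim import CLASS_NAMES, HabitatClassMap, RoadNetwork

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_class_map",
    "read_class_map",
    "write_stack",
    "read_stack",
    "write_roads",
    "read_roads",
    "write_polygons",
    "read_polygons",
]


def write_ascii_grid(path, values: np.ndarray, cell_size: float,
                     origin=(0.0, 0.0), fmt: str = "%.6g") -> None:
    """ESRI ASCII grid; row 0 of ``values`` is the bottom row of the map."""
    values = np.asarray(values)
    nr, nc = values.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values[::-1], fmt=fmt)  # .asc stores top row first


def read_ascii_grid(path) -> tuple[np.ndarray, float, tuple[float, float]]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)[::-1]
    return values, hdr["cellsize"], (hdr["xllcorner"], hdr["yllcorner"])


def write_class_map(path, class_map: HabitatClassMap) -> None:
    """Grid of 1-based class codes plus a JSON legend sidecar."""
    write_ascii_grid(
        path, class_map.classes.astype(int) + 1,
        class_map.cell_size, class_map.origin, fmt="%d",
    )
    legend = {str(i + 1): name for i, name in enumerate(CLASS_NAMES)}
    Path(str(path) + ".legend.json").write_text(json.dumps(legend, indent=1))


def read_class_map(path) -> HabitatClassMap:
    values, cell_size, origin = read_ascii_grid(path)
    return HabitatClassMap(
        classes=values.astype(np.int8) - 1, cell_size=cell_size, origin=origin
    )


def write_stack(directory, stack: CovariateStack) -> None:
    """One ``.asc`` per band plus a band manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.grids.items():
        write_ascii_grid(directory / f"{name}.asc", grid, stack.cell_size, stack.origin)
    manifest = {"bands": list(stack.grids), "cell_size": stack.cell_size,
                "origin": list(stack.origin)}
    (directory / "bands.json").write_text(json.dumps(manifest, indent=1))


def read_stack(directory) -> CovariateStack:
    directory = Path(directory)
    manifest = json.loads((directory / "bands.json").read_text())
    grids = {}
    for name in manifest["bands"]:
        grids[name], _, _ = read_ascii_grid(directory / f"{name}.asc")
    return CovariateStack(
        grids=grids, cell_size=manifest["cell_size"],
        origin=tuple(manifest["origin"]),
    )


def write_roads(path, roads: RoadNetwork) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(line),
            "properties": {"road_class": cls},
        }
        for line, cls in roads.roads
    ]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}
    ))


def read_roads(path) -> RoadNetwork:
    fc = json.loads(Path(path).read_text())
    roads = [
        (LineString(shape(f["geometry"])), f["properties"]["road_class"])
        for f in fc["features"]
    ]
    return RoadNetwork(roads=roads)


def write_polygons(path, geometry, properties: dict | None = None) -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(geometry),
        "properties": properties or {},
    }
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": [feature]}
    ))


def read_polygons(path):
    fc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    return shapely.union_all(geoms) if len(geoms) != 1 else geoms[0]
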