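import math

import numpy as np
import pytest
from shapely.geometry import LineString

from habsel.covariates import (
    AbsentClassError,
    CovariateStack,
    DegenerateMapError,
    EvennessParams,
    PointOutsideRasterError,
    distance_to_class,
    distance_to_roads,
    evenness,
    evenness_index,
    extract,
    signed_forest_distance,
)
from habsel.landscape_sim import CLASS_NAMES, HabitatClassMap, RoadNetwork


def brute_force_distance(class_map, code):
    """All-pairs minimum center-to-center distance oracle."""
    nr, nc = class_map.classes.shape
    cell = class_map.cell_size
    targets = np.argwhere(class_map.classes == code)
    out = np.empty((nr, nc))
    for r in range(nr):
        for c in range(nc):
            d2 = ((targets[:, 0] - r) ** 2 + (targets[:, 1] - c) ** 2).min()
            out[r, c] = math.sqrt(d2) * cell
    return out


class TestDistanceToClass:
    def test_zero_at_target_cells(self, random_map_30):
        d = distance_to_class(random_map_30, "water")
        code = CLASS_NAMES.index("water")
        assert (d[random_map_30.classes == code] == 0).all()

    def test_orthogonal_neighbor_is_cell_size(self):
        classes = np.zeros((3, 3), dtype=np.int8)
        classes[1, 1] = 1
        m = HabitatClassMap(classes, cell_size=30.0)
        d = distance_to_class(m, "agriculture")
        assert d[1, 0] == pytest.approx(30.0)
        assert d[0, 0] == pytest.approx(30.0 * math.sqrt(2))

    def test_matches_brute_force(self, random_map_30):
        for name in ("forest", "developed"):
            d = distance_to_class(random_map_30, name)
            oracle = brute_force_distance(random_map_30, CLASS_NAMES.index(name))
            assert np.abs(d - oracle).max() < 1e-9

    def test_absent_class_error(self):
        m = HabitatClassMap(np.zeros((10, 10), dtype=np.int8), cell_size=30.0)
        with pytest.raises(AbsentClassError):
            distance_to_class(m, "water")

    def test_scaling_with_cell_size(self, random_map_30):
        doubled = HabitatClassMap(
            random_map_30.classes.copy(), cell_size=random_map_30.cell_size * 2
        )
        d1 = distance_to_class(random_map_30, "grassland")
        d2 = distance_to_class(doubled, "grassland")
        np.testing.assert_allclose(d2, 2 * d1)


class TestSignedForestDistance:
    def test_adjacent_nonforest_positive(self):
        classes = np.ones((3, 3), dtype=np.int8)
        classes[1, 1] = 0  # one forest cell
        m = HabitatClassMap(classes, cell_size=30.0)
        d = signed_forest_distance(m)
        assert d[1, 0] == pytest.approx(30.0)

    def test_interior_forest_negative(self):
        # forest block: interior cell 225 m (7.5 cells -> use 8 rows in) from edge
        classes = np.zeros((17, 17), dtype=np.int8)
        classes[0, :] = 1  # single non-forest row at the bottom
        m = HabitatClassMap(classes, cell_size=30.0)
        d = signed_forest_distance(m)
        # row index 8 is 8 cells above the non-forest row minus 0.5? distances
        # are center-to-center: cell (8, j) is 8 cells from row 0 -> 240 m;
        # cell (7, j) -> 210 m; 225 m sits between cells, so check exact values
        assert d[8, 8] == pytest.approx(-240.0)
        assert d[7, 8] == pytest.approx(-210.0)
        assert (d[classes == 0] < 0).all()

    def test_matches_two_sided_brute_force(self, random_map_30):
        d = signed_forest_distance(random_map_30)
        pos = brute_force_distance(random_map_30, 0)
        # oracle for the negative side: distance to nearest non-forest center
        inverted = HabitatClassMap(
            np.where(random_map_30.classes == 0, 0, 1).astype(np.int8),
            cell_size=random_map_30.cell_size,
        )
        neg = brute_force_distance(inverted, 1)
        oracle = np.where(random_map_30.classes == 0, -neg, pos)
        assert np.abs(d - oracle).max() < 1e-9

    def test_sign_partition(self, random_map_30):
        d = signed_forest_distance(random_map_30)
        forest = random_map_30.classes == 0
        assert (d[forest] < 0).all()
        assert (d[~forest] > 0).all()
        assert np.isfinite(d).all()

    def test_degenerate_maps_rejected(self):
        all_forest = HabitatClassMap(np.zeros((10, 10), dtype=np.int8), cell_size=30)
        no_forest = HabitatClassMap(np.ones((10, 10), dtype=np.int8), cell_size=30)
        for m in (all_forest, no_forest):
            with pytest.raises(DegenerateMapError):
                signed_forest_distance(m)


class TestDistanceToRoads:
    def test_cell_center_on_road_vertex(self):
        m = HabitatClassMap(np.zeros((10, 10), dtype=np.int8), cell_size=30.0)
        # vertex exactly at the center of cell (0, 0)
        net = RoadNetwork(roads=[(LineString([(15, 15), (15, 300)]), "major")])
        d = distance_to_roads(m, net, "major")
        assert d[0, 0] == pytest.approx(0.0)

    def test_vertical_road_distance(self):
        m = HabitatClassMap(np.zeros((10, 10), dtype=np.int8), cell_size=30.0)
        net = RoadNetwork(roads=[(LineString([(150, 0), (150, 300)]), "minor")])
        d = distance_to_roads(m, net, "minor")
        # cell centered at x = 300 (col 9, center 285)... col index for x=300:
        # centers are at 15, 45, ..., 285; distance from 285 to 150 is 135
        assert d[0, 9] == pytest.approx(135.0)

    def test_matches_densified_sampling(self):
        rng = np.random.default_rng(5)
        m = HabitatClassMap(np.zeros((20, 20), dtype=np.int8), cell_size=30.0)
        lines = [
            LineString(rng.uniform(0, 600, size=(3, 2))),
            LineString(rng.uniform(0, 600, size=(4, 2))),
        ]
        net = RoadNetwork(roads=[(ln, "major") for ln in lines])
        d = distance_to_roads(m, net, "major")
        # oracle: sample each polyline at 1 m spacing, min point distance
        samples = []
        for ln in lines:
            ts = np.arange(0, ln.length, 1.0)
            samples.extend([ln.interpolate(t) for t in ts])
            samples.append(ln.interpolate(ln.length))
        sample_xy = np.array([[p.x, p.y] for p in samples])
        xs, ys = m.cell_centers()
        for r in range(0, 20, 3):
            for c in range(0, 20, 3):
                dd = np.hypot(sample_xy[:, 0] - xs[c], sample_xy[:, 1] - ys[r]).min()
                assert abs(d[r, c] - dd) < 1.0

    def test_missing_class_gets_diagonal_sentinel(self, caplog):
        m = HabitatClassMap(np.zeros((10, 20), dtype=np.int8), cell_size=30.0)
        net = RoadNetwork(roads=[])
        d = distance_to_roads(m, net, "major")
        diag = math.hypot(20 * 30.0, 10 * 30.0)
        assert (d == diag).all()


class TestEvenness:
    def test_single_class_window_is_zero(self):
        m = HabitatClassMap(np.zeros((20, 20), dtype=np.int8), cell_size=30.0)
        he = evenness(m, EvennessParams(window_radius=90.0))
        np.testing.assert_allclose(he, 0.0)

    def test_equal_share_index_is_one(self):
        assert evenness_index((0.2, 0.2, 0.2, 0.2, 0.2)) == pytest.approx(1.0)

    def test_index_of_study_area_composition(self):
        he = evenness_index((0.54, 0.35, 0.04, 0.02, 0.05))
        assert he == pytest.approx(0.6567, abs=1e-4)

    def test_fast_equals_brute_force_loop(self):
        rng = np.random.default_rng(77)
        m = HabitatClassMap(
            rng.integers(0, 5, size=(50, 50)).astype(np.int8), cell_size=30.0
        )
        radius = 100.0
        he = evenness(m, EvennessParams(window_radius=radius))
        r_cells = radius / 30.0
        oracle = np.empty((50, 50))
        for r in range(50):
            for c in range(50):
                counts = [0] * 5
                lo_r = max(0, r - int(r_cells) - 1)
                hi_r = min(50, r + int(r_cells) + 2)
                for rr in range(lo_r, hi_r):
                    for cc in range(max(0, c - int(r_cells) - 1),
                                    min(50, c + int(r_cells) + 2)):
                        if (rr - r) ** 2 + (cc - c) ** 2 <= r_cells**2:
                            counts[int(m.classes[rr, cc])] += 1
                total = sum(counts)
                p = [ct / total for ct in counts]
                oracle[r, c] = -sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(5)
        assert np.abs(he - oracle).max() < 1e-9

    def test_fft_path_equals_direct_path(self):
        # large-kernel FFT branch must agree with the exact convolution
        rng = np.random.default_rng(3)
        m = HabitatClassMap(
            rng.integers(0, 5, size=(80, 80)).astype(np.int8), cell_size=30.0
        )
        he_big = evenness(m, EvennessParams(window_radius=900.0))  # FFT branch
        # direct oracle on a subsample of cells
        r_cells = 900.0 / 30.0
        for r, c in [(0, 0), (40, 40), (79, 79), (10, 70)]:
            counts = [0] * 5
            for rr in range(80):
                for cc in range(80):
                    if (rr - r) ** 2 + (cc - c) ** 2 <= r_cells**2:
                        counts[int(m.classes[rr, cc])] += 1
            total = sum(counts)
            p = [ct / total for ct in counts]
            expect = -sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(5)
            assert he_big[r, c] == pytest.approx(expect, abs=1e-9)

    def test_range_and_window_validation(self, small_map):
        he = evenness(small_map, EvennessParams(window_radius=150.0))
        assert he.min() >= 0.0 and he.max() <= 1.0
        with pytest.raises(ValueError, match="window_radius"):
            evenness(small_map, EvennessParams(window_radius=10.0))


class TestStackInvariants:
    def test_nonforest_distances_nonnegative_and_zero_on_class(
        self, small_map, small_stack
    ):
        for i, name in enumerate(CLASS_NAMES[1:], start=1):
            grid = small_stack.grids[f"dist_{name}"]
            assert grid.min() >= 0
            assert (grid[small_map.classes == i] == 0).all()

    def test_distance_triangle_union(self, random_map_30):
        # min of two class distances equals distance to the union class
        da = distance_to_class(random_map_30, "water")
        db = distance_to_class(random_map_30, "developed")
        union_codes = (CLASS_NAMES.index("water"), CLASS_NAMES.index("developed"))
        merged = np.where(
            np.isin(random_map_30.classes, union_codes), 1, 0
        ).astype(np.int8)
        m2 = HabitatClassMap(merged, cell_size=random_map_30.cell_size)
        du = distance_to_class(m2, "agriculture")
        np.testing.assert_allclose(np.minimum(da, db), du, atol=1e-9)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="share one shape"):
            CovariateStack(
                grids={"a": np.zeros((3, 3)), "b": np.zeros((4, 3))}, cell_size=30.0
            )


class TestExtract:
    def test_point_at_cell_center(self, small_stack):
        x = 5 * 30.0 + 15.0
        y = 7 * 30.0 + 15.0
        rows = extract(small_stack, [(x, y)])
        for name, grid in small_stack.grids.items():
            assert rows[name].iloc[0] == grid[7, 5]

    def test_point_just_inside_edge(self, small_stack):
        x1 = small_stack.extent[2]
        rows = extract(small_stack, [(x1 - 0.001, 0.001)])
        for name, grid in small_stack.grids.items():
            assert rows[name].iloc[0] == grid[0, -1]

    def test_boundary_point_maps_to_edge_cell(self, small_stack):
        x1, y1 = small_stack.extent[2:]
        rows = extract(small_stack, [(x1, y1)])
        for name, grid in small_stack.grids.items():
            assert rows[name].iloc[0] == grid[-1, -1]

    def test_outside_point_raises_with_index(self, small_stack):
        with pytest.raises(PointOutsideRasterError) as err:
            extract(small_stack, [(15.0, 15.0), (-5.0, 15.0)])
        assert err.value.index == 1

    def test_matches_index_arithmetic(self, small_stack):
        rng = np.random.default_rng(11)
        x0, y0, x1, y1 = small_stack.extent
        pts = np.column_stack([
            rng.uniform(x0, x1, 100), rng.uniform(y0, y1, 100)
        ])
        rows = extract(small_stack, pts)
        for i, (x, y) in enumerate(pts):
            col = min(int((x - x0) // 30.0), small_stack.shape[1] - 1)
            row = min(int((y - y0) // 30.0), small_stack.shape[0] - 1)
            for name, grid in small_stack.grids.items():
                assert rows[name].iloc[i] == grid[row, col]
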