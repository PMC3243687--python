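import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, box

from rspfit.covariates import (
    CovariateSpec,
    assemble_covariates,
    distance_to_class,
    distance_to_edge,
    distance_to_lines,
    focal_proportion,
    heterogeneity,
    local_indicators,
    park_covariates,
    table1_specs,
)
from rspfit.landscape import CLASS_CODES, LandscapeBundle
from tests.conftest import make_grid

FOREST = CLASS_CODES["forest"]
GRASS = CLASS_CODES["grassland"]
AG = CLASS_CODES["agriculture"]
CERRADO = CLASS_CODES["cerrado"]


def brute_force_class_distance(grid, classes, points):
    """Oracle: min distance from the point's cell center to any target-cell
    center (0 inside a target cell)."""
    xs, ys = grid.cell_centers()
    gx, gy = np.meshgrid(xs, ys)
    mask = np.isin(grid.codes, [CLASS_CODES[c] for c in classes])
    cx, cy = gx[mask], gy[mask]
    row, col = grid.cell_index(points)
    out = np.empty(len(points))
    for i, (r, c) in enumerate(zip(row, col)):
        if mask[r, c]:
            out[i] = 0.0
        else:
            out[i] = np.min(np.hypot(cx - gx[r, c], cy - gy[r, c]))
    return out


class TestLineDistances:
    def test_point_on_vertex_is_zero(self):
        line = LineString([(0, 0), (100, 0)])
        assert distance_to_lines([[0, 0]], [line])[0] == 0.0

    def test_vertical_line_horizontal_offset(self):
        line = LineString([(0, -1000), (0, 1000)])
        assert distance_to_lines([[100, 50]], [line], units="m")[0] == pytest.approx(100.0)
        assert distance_to_lines([[100, 50]], [line], units="km")[0] == pytest.approx(0.1)

    def test_beyond_endpoint_uses_endpoint(self):
        line = LineString([(0, 0), (10, 0)])
        # oracle: dense sampling of the segment
        dense = np.linspace([0, 0], [10, 0], 5001)
        oracle = np.hypot(*(dense - [20, 0]).T).min()
        assert distance_to_lines([[20, 0]], [line])[0] == pytest.approx(oracle, abs=1e-6)

    def test_empty_set_raises_with_name(self):
        with pytest.raises(ValueError, match="roadDist"):
            distance_to_lines([[0, 0]], [], name="roadDist")

    def test_km_and_m_unit_consistency(self):
        lines = [LineString([(0, 0), (500, 700)]), LineString([(900, 0), (900, 900)])]
        pts = np.random.default_rng(0).uniform(0, 1000, (40, 2))
        m = distance_to_lines(pts, lines, units="m")
        km = distance_to_lines(pts, lines, units="km")
        assert np.array_equal(km * 1000.0, m)


class TestClassDistances:
    def test_inside_target_cell_is_zero(self):
        grid = make_grid(np.full((10, 10), AG))
        assert distance_to_class([[150, 150]], grid, ["agriculture"])[0] == 0.0

    def test_absent_class_infinite_with_warning(self, uniform_grassland_grid):
        with pytest.warns(UserWarning, match="infinite"):
            d = distance_to_class([[100, 100]], uniform_grassland_grid,
                                  ["forest", "cerrado"])
        assert np.isinf(d[0])

    def test_single_forest_cell_10_cells_east(self):
        codes = np.full((21, 21), GRASS)
        codes[10, 10] = FOREST
        grid = make_grid(codes)
        # point in the cell 10 columns east of the forest cell
        x = (10 + 10) * 30.0 + 15.0
        y = grid.origin[1] - (10 * 30.0 + 15.0)
        assert distance_to_class([[x, y]], grid, ["forest"])[0] == pytest.approx(0.300)

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(4):
            codes = rng.integers(0, 8, size=(50, 50)).astype(np.int16)
            grid = make_grid(codes)
            pts = rng.uniform(1.0, 50 * 30.0 - 1.0, size=(100, 2))
            for classes in (["forest"], ["agriculture", "pasture"]):
                got = distance_to_class(pts, grid, classes, units="km") * 1000.0
                want = brute_force_class_distance(grid, classes, pts)
                assert np.max(np.abs(got - want)) < 15.0  # half a cell


class TestEdgeDistance:
    def test_uniform_grid_infinite(self, uniform_grassland_grid):
        with pytest.warns(UserWarning, match="infinite"):
            d = distance_to_edge([[100, 100]], uniform_grassland_grid)
        assert np.isinf(d[0])

    def test_point_on_boundary_row_is_zero(self):
        codes = np.full((10, 10), GRASS)
        codes[:, 5:] = AG
        grid = make_grid(codes)
        assert distance_to_edge([[5 * 30 - 15, 150]], grid)[0] == 0.0

    def test_two_half_planes(self):
        # split at x = 1500 m on a 100x100 grid of 30-m cells
        codes = np.full((100, 100), GRASS)
        codes[:, 50:] = AG
        grid = make_grid(codes)
        d = distance_to_edge([[600.0, 1500.0]], grid)[0]
        assert d == pytest.approx(0.9, abs=0.0301)  # one cell width


class TestPark:
    PARK = box(1000, 1000, 3000, 3000)

    def test_centroid_inside(self):
        ind, dist = park_covariates([[2000, 2000]], self.PARK)
        assert (ind[0], dist[0]) == (1, 0.0)

    def test_outside_distance(self):
        ind, dist = park_covariates([[5000, 2000]], self.PARK)
        # oracle: dense boundary sampling
        t = np.linspace(0, self.PARK.exterior.length, 20001)
        bd = np.array([self.PARK.exterior.interpolate(u).coords[0] for u in t])
        want = np.hypot(*(bd - [5000, 2000]).T).min()
        assert ind[0] == 0
        assert dist[0] == pytest.approx(2000.0, abs=1e-6)
        assert dist[0] == pytest.approx(want, abs=1e-3)

    def test_boundary_counts_as_inside(self):
        ind, dist = park_covariates([[1000, 2000]], self.PARK)
        assert (ind[0], dist[0]) == (1, 0.0)


class TestLocalIndicators:
    def make_features(self, grid):
        from rspfit.landscape import FeatureSet

        return FeatureSet(
            roads=[LineString([(0, 300), (600, 300)])], main_roads=[],
            rivers=[], springs=np.array([[0.0, 300.0]]),
            park=box(0, 0, 60, 60), elevation=np.zeros(grid.shape))

    def test_spring_buffer_closed_at_500m(self, uniform_grassland_grid):
        feats = self.make_features(uniform_grassland_grid)
        out = local_indicators([[499.0, 300.0], [501.0, 300.0]], feats,
                               uniform_grassland_grid)
        assert out["spring"].tolist() == [1, 0]

    def test_road_buffer_closed_at_30m(self, uniform_grassland_grid):
        feats = self.make_features(uniform_grassland_grid)
        out = local_indicators([[300.0, 330.0], [300.0, 331.0]], feats, uniform_grassland_grid)
        assert out["road"].tolist() == [1, 0]

    def test_class_indicators_partition(self):
        codes = np.full((4, 4), GRASS)
        codes[0, 0] = CLASS_CODES["marsh"]
        grid = make_grid(codes)
        feats = self.make_features(grid)
        out = local_indicators([[15.0, grid.origin[1] - 15.0]], feats, grid)
        class_cols = [c for c in out.columns if c in CLASS_CODES]
        assert out.loc[0, "marsh"] == 1
        assert out.loc[0, class_cols].sum() == 1

    def test_point_outside_extent_lists_ids(self, uniform_grassland_grid):
        feats = self.make_features(uniform_grassland_grid)
        with pytest.raises(ValueError, match=r"\[1\]"):
            local_indicators([[10.0, 10.0], [99999.0, 10.0]], feats, uniform_grassland_grid)


class TestFocalProportion:
    def test_uniform_grids(self, uniform_grassland_grid):
        natural = ("forest", "cerrado", "open cerrado", "grassland", "marsh")
        p = focal_proportion([[300, 300]], uniform_grassland_grid, natural,
                             window_area_km2=0.05)
        assert p[0] == 1.0
        ag = make_grid(np.full((20, 20), AG))
        assert focal_proportion([[300, 300]], ag, natural, window_area_km2=0.05)[0] == 0.0

    def test_half_plane_point_on_divide(self):
        codes = np.full((80, 80), AG)
        codes[:, :40] = FOREST
        grid = make_grid(codes)
        mid_x = 40 * 30.0
        p = focal_proportion([[mid_x, 1200.0]], grid, ["forest", "cerrado"],
                             window_area_km2=0.5)
        # exact disc-cell count oracle
        r = np.sqrt(0.5e6 / np.pi)
        xs, ys = grid.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        in_disc = (gx - mid_x) ** 2 + (gy - 1200.0) ** 2 <= r ** 2
        want = (in_disc & (grid.codes == FOREST)).sum() / in_disc.sum()
        assert p[0] == pytest.approx(want, abs=1e-12)
        assert p[0] == pytest.approx(0.5, abs=1.0 / in_disc.sum() * 12)

    def test_complement_identity(self, small_landscape):
        grid = small_landscape.habitat
        rng = np.random.default_rng(7)
        pts = rng.uniform(2000, 7000, size=(50, 2))  # interior points
        a = focal_proportion(pts, grid, ["forest", "cerrado"], window_area_km2=1.4)
        classes_c = [c for c in CLASS_CODES if c not in ("forest", "cerrado")]
        b = focal_proportion(pts, grid, classes_c, window_area_km2=1.4)
        assert np.max(np.abs(a + b - 1.0)) < 1e-9

    def test_window_smaller_than_cell_rejected(self, uniform_grassland_grid):
        with pytest.raises(ValueError, match="smaller than one"):
            focal_proportion([[300, 300]], uniform_grassland_grid, ["grassland"],
                             radius_m=10.0)


class TestHeterogeneity:
    def test_uniform_grid_is_one(self, uniform_grassland_grid):
        out = heterogeneity([[300, 300]], uniform_grassland_grid, [100, 200, 400])
        assert (out.iloc[0] == 1).all()

    def test_monotone_in_radius(self, small_landscape):
        rng = np.random.default_rng(3)
        pts = rng.uniform(1500, 7500, size=(30, 2))
        out = heterogeneity(pts, small_landscape.habitat, [250, 500, 1000])
        v = out.to_numpy()
        assert np.all(v[:, 0] <= v[:, 1]) and np.all(v[:, 1] <= v[:, 2])

    def test_checkerboard_sees_both_classes(self):
        codes = np.indices((20, 20)).sum(axis=0) % 2
        codes = np.where(codes == 1, GRASS, AG).astype(np.int16)
        grid = make_grid(codes)
        out = heterogeneity([[300, 300]], grid, [45.0])
        assert out.iloc[0, 0] == 2


class TestAssemble:
    def test_empty_specs_gives_empty_table(self, small_landscape):
        out = assemble_covariates([[4000, 4000]], small_landscape, [])
        assert out.shape == (1, 0)

    def test_full_table1_suite_has_24_columns(self, small_landscape):
        specs = table1_specs()
        rng = np.random.default_rng(0)
        pts = rng.uniform(1000, 8000, size=(20, 2))
        out = assemble_covariates(pts, small_landscape, specs)
        assert out.shape == (20, 24)
        assert list(out.columns) == [s.name for s in specs]
        assert out.notna().all().all()
        for col in ("closed", "open", "natural", "nocrop"):
            assert out[col].between(0, 1).all()
        for col in ("park", "spring", "road", "forest", "grassland"):
            assert set(out[col].unique()) <= {0, 1}

    def test_duplicate_names_rejected(self, small_landscape):
        specs = [CovariateSpec("x", "elevation"), CovariateSpec("x", "elevation")]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_covariates([[4000, 4000]], small_landscape, specs)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 8, size=(40, 40)).astype(np.int16)
        pts = rng.uniform(100, 1100, size=(25, 2))
        shift = np.array([12345.0, -6789.0])
        g0 = make_grid(codes)
        g1 = make_grid(codes)
        g1.origin = (g0.origin[0] + shift[0], g0.origin[1] + shift[1])
        for classes in (["forest"], ["agriculture"]):
            d0 = distance_to_class(pts, g0, classes)
            d1 = distance_to_class(pts + shift, g1, classes)
            assert np.allclose(d0, d1)
        p0 = focal_proportion(pts, g0, ["forest", "cerrado"], window_area_km2=0.3)
        p1 = focal_proportion(pts + shift, g1, ["forest", "cerrado"], window_area_km2=0.3)
        assert np.allclose(p0, p1)
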