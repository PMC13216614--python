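"""Equal-area grid geometry, band/zone assignment and area accounting."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from oceangap import geogrid
from oceangap.geogrid import (DEPTH_ZONES, aggregate_covariates, assign_band,
                              assign_cell, assign_depth_zone, build_grid,
                              gap_summary)
from oceangap.rasters import EARTH_RADIUS_KM, Raster, cell_areas_km2

SPHERE_KM2 = 4 * np.pi * EARTH_RADIUS_KM ** 2


class TestGridGeometry:
    @pytest.mark.parametrize("res", [0, 1, 2, 3, 4])
    def test_aperture4_cell_count_law(self, res):
        assert len(build_grid(res)) == 10 * 4 ** res + 2

    def test_resolution0_is_all_pentagons(self):
        g = build_grid(0)
        assert len(g) == 12 and all(c.is_pentagon for c in g.cells)

    def test_resolution3_cell_count_and_area(self, grid3):
        areas = np.array([c.area_km2 for c in grid3.cells])
        assert len(grid3) == 642
        assert areas.mean() == pytest.approx(SPHERE_KM2 / 642, rel=1e-9)
        # "about 800,000 km^2" analysis cells
        assert areas.mean() == pytest.approx(8.0e5, rel=0.01)

    def test_area_partition_of_sphere(self, grid3):
        areas = np.array([c.area_km2 for c in grid3.cells])
        assert areas.sum() == pytest.approx(SPHERE_KM2, rel=1e-4)

    def test_hexagons_equal_pentagons_five_sixths(self, grid3):
        areas = np.array([c.area_km2 for c in grid3.cells])
        pent = np.array([c.is_pentagon for c in grid3.cells])
        assert pent.sum() == 12
        hexes = areas[~pent]
        assert hexes.std() / hexes.mean() < 1e-3
        assert areas[pent].mean() / hexes.mean() == pytest.approx(5 / 6, rel=5e-3)

    def test_boundaries_closed(self, grid3):
        for c in grid3.cells[:50]:
            assert c.boundary[0] == c.boundary[-1]
            assert len(c.boundary) >= 6


class TestAssignCell:
    def test_own_center_maps_to_cell(self, grid3):
        lats = np.array([c.center[0] for c in grid3.cells])
        lons = np.array([c.center[1] for c in grid3.cells])
        ids = assign_cell(grid3, lats, lons)
        assert np.array_equal(ids, np.arange(len(grid3)))

    def test_north_pole_is_pentagon(self, grid3):
        cid = assign_cell(grid3, 90.0, 0.0)
        assert grid3.cells[cid].is_pentagon

    def test_agrees_with_point_in_polygon_oracle(self, grid3):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(10_000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        lat = np.degrees(np.arcsin(u[:, 2]))
        lon = np.degrees(np.arctan2(u[:, 1], u[:, 0]))
        ids = assign_cell(grid3, lat, lon)
        polys = {}

        def contains(cell, p):
            cc = cell.center_xyz
            if np.dot(p, cc) <= 0:
                return False
            if cell.cell_id not in polys:
                ex = np.array([0.0, 0.0, 1.0]) if abs(cc[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
                ex = ex - np.dot(ex, cc) * cc
                ex /= np.linalg.norm(ex)
                ey = np.cross(cc, ex)
                ring = []
                for la, lo in cell.boundary[:-1]:
                    v = np.array([np.cos(np.radians(la)) * np.cos(np.radians(lo)),
                                  np.cos(np.radians(la)) * np.sin(np.radians(lo)),
                                  np.sin(np.radians(la))])
                    v = v / np.dot(v, cc)       # gnomonic projection
                    ring.append((np.dot(v, ex), np.dot(v, ey)))
                polys[cell.cell_id] = (Polygon(ring).buffer(1e-9), cc, ex, ey)
            poly, cc, ex, ey = polys[cell.cell_id]
            q = p / np.dot(p, cc)
            return poly.contains(Point(np.dot(q, ex), np.dot(q, ey)))

        agree = sum(contains(grid3.cells[i], u[k]) for k, i in enumerate(ids))
        assert agree / 10_000 >= 0.999

    def test_every_point_assigned(self, grid3):
        rng = np.random.default_rng(1)
        lat = rng.uniform(-90, 90, 2000)
        lon = rng.uniform(-180, 180, 2000)
        ids = assign_cell(grid3, lat, lon)
        assert np.all((ids >= 0) & (ids < len(grid3)))


class TestBandsAndZones:
    @pytest.mark.parametrize("lat,band", [(0.0, 18), (-90.0, 0), (90.0, 35),
                                          (4.999, 18), (5.0, 19), (-0.001, 17)])
    def test_half_open_band_assignment(self, lat, band):
        assert assign_band(lat) == band

    def test_band_out_of_range_raises(self):
        with pytest.raises(ValueError):
            assign_band(91.0)

    @pytest.mark.parametrize("depth,zone", [
        (150.0, "shallow"), (0.0, "shallow"), (199.999, "shallow"),
        (200.0, "mesopelagic"), (499.999, "mesopelagic"),
        (500.0, "deep"), (11000.0, "deep"), (np.nan, "unknown")])
    def test_zone_boundaries(self, depth, zone):
        assert assign_depth_zone(depth) == zone

    def test_depth_domain_errors(self):
        with pytest.raises(ValueError):
            assign_depth_zone(11000.1)
        with pytest.raises(ValueError):
            assign_depth_zone(-1.0)

    def test_zones_partition_depth_domain(self):
        rng = np.random.default_rng(2)
        zones = assign_depth_zone(rng.uniform(0, 11000, 5000))
        assert set(np.unique(zones)) <= set(DEPTH_ZONES)


class TestAggregateCovariates:
    def test_flat_shallow_world_shelf_equals_ocean(self):
        bathy = Raster(np.full((36, 72), 100.0), resolution=5.0)
        tab = aggregate_covariates("bands", bathy)
        assert np.allclose(tab["shelf_area_km2"], tab["ocean_area_km2"])
        assert np.allclose(tab["margin_area_km2"], 0.0)

    def test_band_areas_sum_to_sphere_without_land(self):
        bathy = Raster(np.full((36, 72), 4000.0), resolution=5.0)
        tab = aggregate_covariates("bands", bathy)
        assert tab["ocean_area_km2"].sum() == pytest.approx(SPHERE_KM2, rel=1e-6)

    def test_hand_summed_shelf_and_margin_areas(self):
        vals = np.full((10, 10), 2000.0)
        vals[0, :3] = 100.0          # 3 shelf cells in the southernmost row
        vals[1, :2] = 4000.0         # 2 cells below the margin ceiling
        vals[2, 0] = np.nan          # land
        bathy = Raster(vals, lat_min=0.0, lon_min=0.0, resolution=1.0)
        areas = cell_areas_km2(bathy)
        tab = aggregate_covariates("bands", bathy)
        row = tab.iloc[18]           # band [0, 5) holds rows 0..4
        exp_ocean = areas[:5].sum() - areas[2, 0]
        assert row["ocean_area_km2"] == pytest.approx(exp_ocean)
        assert row["shelf_area_km2"] == pytest.approx(areas[0, :3].sum())
        exp_margin = exp_ocean - areas[0, :3].sum() - areas[1, :2].sum()
        assert row["margin_area_km2"] == pytest.approx(exp_margin)
        assert row["max_depth_m"] == pytest.approx(4000.0)

    def test_nodata_layer_cells_excluded_from_means(self):
        bathy = Raster(np.full((4, 4), 1000.0), lat_min=0, lon_min=0, resolution=1.0)
        lay = np.full((4, 4), 10.0)
        lay[0, 0] = np.nan
        lay[0, 1] = 30.0
        tab = aggregate_covariates("bands", bathy, {"temperature": Raster(
            lay, lat_min=0, lon_min=0, resolution=1.0)})
        row = tab.iloc[18]
        a = cell_areas_km2(bathy)
        expected = (30.0 * a[0, 1] + 10.0 * (a[:4].sum() - a[0, 0] - a[0, 1])) \
            / (a[:4].sum() - a[0, 0])
        assert row["temperature_mean"] == pytest.approx(expected)
        assert row["temperature_max"] == pytest.approx(30.0)


class TestGapSummary:
    def _summ(self, n_records, areas, zone="shallow"):
        return pd.DataFrame({"depth_zone": zone, "n_records": n_records,
                             "ocean_area_km2": areas})

    def test_no_gaps_when_all_sampled(self):
        out = gap_summary(self._summ([60, 70, 80], [1.0, 2.0, 3.0]))
        assert out["gap_fraction"].iloc[0] == 0.0

    def test_single_gap_cell_fraction(self):
        out = gap_summary(self._summ([60, 10, 80], [1.0, 2.0, 3.0]))
        assert out["gap_fraction"].iloc[0] == pytest.approx(2.0 / 6.0)

    def test_threshold_is_strict_less_than(self):
        out = gap_summary(self._summ([50, 49], [1.0, 1.0]))
        assert out["gap_fraction"].iloc[0] == pytest.approx(0.5)
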