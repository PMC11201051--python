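"""Geodesy, suitability classification, area accounting, range algebra,
and centroid migration."""

import numpy as np
import pytest

from nichemax.geodesy import (EARTH_RADIUS_KM, band_area_km2, haversine_km,
                              initial_bearing_deg)
from nichemax.grid_io import AlignmentError, EnvGrid, GridHeader
from nichemax.habitat import (AreaSummary, EmptyRangeError, binary_map,
                              cell_area_km2, centroid, change_map,
                              class_areas, classify, migration_vector)


class TestGeodesy:
    def test_one_degree_latitude_arc(self):
        # closed form 2*pi*R/360 = 111.195 km
        assert haversine_km(100, 30, 100, 31) == pytest.approx(
            2 * np.pi * EARTH_RADIUS_KM / 360, rel=1e-9)

    def test_distance_symmetric_and_triangle_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            lons = rng.uniform(-180, 180, 3)
            lats = rng.uniform(-85, 85, 3)
            d01 = haversine_km(lons[0], lats[0], lons[1], lats[1])
            d10 = haversine_km(lons[1], lats[1], lons[0], lats[0])
            d12 = haversine_km(lons[1], lats[1], lons[2], lats[2])
            d02 = haversine_km(lons[0], lats[0], lons[2], lats[2])
            assert d01 == pytest.approx(d10, rel=1e-12)
            assert d02 <= d01 + d12 + 1e-9

    def test_bearing_in_range_and_cardinal_directions(self):
        assert initial_bearing_deg(100, 30, 100, 31) == pytest.approx(0.0)
        assert initial_bearing_deg(100, 0, 101, 0) == pytest.approx(90.0)
        assert 0 <= initial_bearing_deg(109.4, 31.9, 107.2, 31.7) < 360


class TestCellArea:
    def test_equatorial_one_degree_cell(self):
        # R^2 * (pi/180) * sin(1 deg) ~ 12364 km^2
        h = GridHeader(1, 1, 0.0, 0.0, 1.0)
        assert cell_area_km2(h, 0) == pytest.approx(12364.0, abs=2.0)

    def test_equal_latitude_rows_equal_and_poleward_decrease(self):
        h = GridHeader(4, 5, 100.0, 30.0, 0.5)
        areas = [cell_area_km2(h, r) for r in range(5)]
        assert areas == sorted(areas)  # row 0 = north = smallest here
        assert len(set(np.round(areas, 9))) == 5

    def test_hemisphere_mirror_rows_equal(self):
        # one grid spanning the equator: rows at +-lat have equal areas
        h = GridHeader(1, 2, 0.0, -1.0, 1.0)
        assert cell_area_km2(h, 0) == pytest.approx(cell_area_km2(h, 1),
                                                    rel=1e-12)


class TestClassify:
    def test_band_assignment(self, header3):
        vals = np.array([[0.05, 0.2, 0.4], [0.6, 0.0, 0.09999],
                         [0.1, 0.3, 0.5]])
        cl = classify(EnvGrid(header3, "p", vals))
        v = cl.class_grid.values
        assert v[0].tolist() == [0, 1, 2]
        assert v[1].tolist() == [3, 0, 0]
        # boundaries: 0.1 -> low, 0.3 -> medium, 0.5 -> high
        assert v[2].tolist() == [1, 2, 3]

    def test_out_of_range_value_rejected(self, header3):
        vals = np.full((3, 3), 0.5)
        vals[0, 0] = 1.2
        with pytest.raises(ValueError):
            classify(EnvGrid(header3, "p", vals))

    def test_nodata_propagates(self, header3):
        vals = np.full((3, 3), 0.4)
        vals[2, 2] = np.nan
        cl = classify(EnvGrid(header3, "p", vals))
        assert np.isnan(cl.class_grid.values[2, 2])
        assert cl.counts()["medium"] == 8


class TestAreas:
    def test_area_conservation(self, header3):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 1, (3, 3))
        vals[1, 2] = np.nan
        grid = EnvGrid(header3, "p", vals)
        summary = class_areas(classify(grid))
        masked_total = sum(cell_area_km2(header3, r) for r in range(3)
                           for c in range(3) if not np.isnan(vals[r, c])) / 1e4
        assert summary.total + summary.unsuitable == pytest.approx(
            masked_total, rel=1e-9)

    def test_empty_class_zero(self, header3):
        summary = class_areas(classify(EnvGrid(header3, "p",
                                               np.zeros((3, 3)))))
        assert summary.low == summary.medium == summary.high == 0.0

    def test_signed_deltas_vs_baseline(self):
        cur = AreaSummary(700.0, 100.0, 50.0, 30.0, period="current")
        fut = AreaSummary(690.0, 105.0, 48.0, 37.0, period="future")
        d = fut.delta_vs(cur)
        assert d.deltas["total"] == pytest.approx(10.0)
        assert d.deltas["unsuitable"] == pytest.approx(-10.0)
        assert "(+10.00)" in d.to_row()["total_suitable"]


class TestBinaryAndChange:
    def test_strict_threshold(self, header3):
        vals = np.array([[0.5, 0.51, 0.49]] * 3)
        b = binary_map(EnvGrid(header3, "p", vals))
        assert b.grid.values[0].tolist() == [0, 1, 0]

    def test_binary_area_equals_high_class_area(self, header3):
        rng = np.random.default_rng(9)
        grid = EnvGrid(header3, "p", rng.uniform(0, 1, (3, 3)))
        high = class_areas(classify(grid)).high
        # p == 0.5 exactly has measure zero under a continuous draw, so
        # the strict binary rule and the closed high band agree
        assert binary_map(grid).area_1e4km2() == pytest.approx(high, rel=1e-12)

    def test_change_map_identities(self, header3):
        rng = np.random.default_rng(10)
        cur = binary_map(EnvGrid(header3, "c", rng.uniform(0, 1, (3, 3))))
        fut = binary_map(EnvGrid(header3, "f", rng.uniform(0, 1, (3, 3))))
        cm = change_map(cur, fut)
        assert cm.retention + cm.contraction == pytest.approx(
            cur.area_1e4km2(), rel=1e-12)
        assert cm.retention + cm.expansion == pytest.approx(
            fut.area_1e4km2(), rel=1e-12)
        assert cm.net == pytest.approx(cm.expansion - cm.contraction)

    def test_identical_maps_no_change(self, header3):
        grid = EnvGrid(header3, "p", np.full((3, 3), 0.7))
        cm = change_map(binary_map(grid), binary_map(grid))
        assert cm.expansion == cm.contraction == 0.0
        assert cm.net == 0.0

    def test_header_mismatch_raises(self, header3):
        a = binary_map(EnvGrid(header3, "a", np.zeros((3, 3))))
        h2 = GridHeader(3, 3, 0.0, 0.0, 1.0)
        b = binary_map(EnvGrid(h2, "b", np.zeros((3, 3))))
        with pytest.raises(AlignmentError):
            change_map(a, b)


class TestCentroid:
    def test_single_cell_gives_its_centre(self, header3):
        vals = np.zeros((3, 3))
        vals[0, 1] = 1.0
        c = centroid(binary_map(EnvGrid(header3, "p", vals * 0.9)))
        lon, lat = header3.cell_center(0, 1)
        assert c.longitude == pytest.approx(lon, abs=1e-12)
        assert c.latitude == pytest.approx(lat, abs=1e-12)

    def test_symmetric_cells_average_longitude(self, header3):
        vals = np.zeros((3, 3))
        vals[1, 0] = vals[1, 2] = 1.0
        c = centroid(binary_map(EnvGrid(header3, "p", vals * 0.9)))
        assert c.longitude == pytest.approx(101.5)

    def test_area_weighting_pulls_toward_equator(self, header3):
        # two cells in rows 0 (north, smaller) and 2 (south, larger)
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[2, 1] = 1.0
        b = binary_map(EnvGrid(header3, "p", vals * 0.9))
        cw = centroid(b, area_weighted=True)
        cu = centroid(b, area_weighted=False)
        a_n = cell_area_km2(header3, 0)
        a_s = cell_area_km2(header3, 2)
        expected = (32.5 * a_n + 30.5 * a_s) / (a_n + a_s)
        assert cw.latitude == pytest.approx(expected, rel=1e-12)
        assert cw.latitude < cu.latitude == pytest.approx(31.5)

    def test_empty_range_raises(self, header3):
        with pytest.raises(EmptyRangeError):
            centroid(binary_map(EnvGrid(header3, "p", np.zeros((3, 3)))))

    def test_migration_zero_for_identical_points(self, header3):
        vals = np.zeros((3, 3))
        vals[1, 1] = 1.0
        c = centroid(binary_map(EnvGrid(header3, "p", vals * 0.9)))
        mv = migration_vector(c, c)
        assert mv.distance_km == 0.0
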