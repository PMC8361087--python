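"""Trait-map construction: inversion, IDW interpolation, masks, comparison."""

import numpy as np
import pytest

from phototrait.datasets import NormalizationParams
from phototrait.mapping import (
    PointPrediction,
    TraitGrid,
    compare_grids,
    deduplicate_against_training,
    idw_grid,
    invert_targets,
    latitudinal_profile,
    quantile_range_grid,
    resample_bilinear,
)
from phototrait.rasters import Raster, haversine_km


def pt(i, lat, lon, value):
    return PointPrediction(f"p{i}", lat, lon, value)


BOUNDS = (0.0, 0.0, 10.0, 10.0)  # west, south, east, north


class TestInvertTargets:
    def test_boundaries(self):
        p = NormalizationParams(-1.0, 2.0)
        assert invert_targets(0.0, p) == pytest.approx(10.0 ** -1)
        assert invert_targets(1.0, p) == pytest.approx(10.0 ** 2)

    def test_roundtrip(self, rng):
        from phototrait.datasets import normalize

        p = NormalizationParams(-1.0, 2.0)
        y = rng.uniform(0, 1, 100)
        back = normalize(np.log10(invert_targets(y, p)), p)
        np.testing.assert_allclose(back, y, atol=1e-12)


class TestDeduplicate:
    def test_empty_training_ids_identity(self):
        pts = [pt(i, 1.0, 1.0, 2.0) for i in range(5)]
        assert deduplicate_against_training(pts, set()) == pts

    def test_full_overlap_empty(self):
        pts = [pt(i, 1.0, 1.0, 2.0) for i in range(5)]
        assert deduplicate_against_training(pts, {p.record_id for p in pts}) == []

    def test_partial_overlap(self):
        pts = [pt(i, 1.0, 1.0, 2.0) for i in range(10)]
        out = deduplicate_against_training(pts, {"p0", "p3", "p7"})
        assert [p.record_id for p in out] == [
            f"p{i}" for i in range(10) if i not in (0, 3, 7)
        ]


class TestIdwGrid:
    def test_single_point_constant_field(self):
        grid = idw_grid([pt(0, 5.0, 5.0, 3.5)], resolution_deg=1.0,
                        buffer_km=10000.0, bounds=BOUNDS)
        assert grid.mask.all()
        np.testing.assert_allclose(grid.values, 3.5)

    def test_exact_hit_takes_point_value(self):
        # cell centers at 0.5, 1.5, ...: put a point exactly on one
        pts = [pt(0, 5.5, 5.5, 9.0), pt(1, 0.5, 0.5, 1.0)]
        grid = idw_grid(pts, resolution_deg=1.0, buffer_km=10000.0, bounds=BOUNDS)
        lats, lons = grid.cell_centers()
        row = int(np.argmin(np.abs(lats - 5.5)))
        col = int(np.argmin(np.abs(lons - 5.5)))
        assert grid.values[row, col] == 9.0

    def test_colocated_points_averaged(self):
        pts = [pt(0, 5.5, 5.5, 2.0), pt(1, 5.5, 5.5, 4.0), pt(2, 0.5, 9.5, 1.0)]
        grid = idw_grid(pts, resolution_deg=1.0, buffer_km=10000.0, bounds=BOUNDS)
        lats, lons = grid.cell_centers()
        row = int(np.argmin(np.abs(lats - 5.5)))
        col = int(np.argmin(np.abs(lons - 5.5)))
        assert grid.values[row, col] == pytest.approx(3.0)

    def test_convex_combination_bound(self, rng):
        pts = [pt(i, float(rng.uniform(1, 9)), float(rng.uniform(1, 9)),
                  float(rng.uniform(2, 8))) for i in range(15)]
        grid = idw_grid(pts, resolution_deg=0.5, buffer_km=10000.0, bounds=BOUNDS)
        vals = [p.value for p in pts]
        assert grid.values[grid.mask].min() >= min(vals) - 1e-12
        assert grid.values[grid.mask].max() <= max(vals) + 1e-12

    def test_two_point_hand_oracle(self):
        """Every cell matches a hand-computed two-term weighted mean."""
        p1, p2 = pt(0, 2.0, 3.0, 10.0), pt(1, 8.0, 7.0, 20.0)
        grid = idw_grid([p1, p2], resolution_deg=0.5, power=2.0,
                        buffer_km=100000.0, bounds=BOUNDS)
        lats, lons = grid.cell_centers()
        for i, lat in enumerate(lats):
            for j, lon in enumerate(lons):
                d1 = haversine_km(lat, lon, p1.lat, p1.lon)
                d2 = haversine_km(lat, lon, p2.lat, p2.lon)
                expected = (10.0 / d1**2 + 20.0 / d2**2) / (1 / d1**2 + 1 / d2**2)
                assert grid.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_order_invariance(self, rng):
        pts = [pt(i, float(rng.uniform(1, 9)), float(rng.uniform(1, 9)),
                  float(rng.uniform(1, 5))) for i in range(8)]
        a = idw_grid(pts, resolution_deg=1.0, buffer_km=10000.0, bounds=BOUNDS)
        b = idw_grid(pts[::-1], resolution_deg=1.0, buffer_km=10000.0, bounds=BOUNDS)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_buffer_masks_distant_cells(self):
        grid = idw_grid([pt(0, 5.0, 5.0, 1.0)], resolution_deg=1.0,
                        buffer_km=150.0, bounds=BOUNDS)
        assert grid.mask.any() and not grid.mask.all()

    def test_buffer_monotone(self):
        pts = [pt(0, 2.0, 2.0, 1.0), pt(1, 8.0, 8.0, 2.0)]
        counts = [
            int(idw_grid(pts, resolution_deg=0.5, buffer_km=b, bounds=BOUNDS).mask.sum())
            for b in (50.0, 100.0, 200.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    def test_land_mask_applied(self):
        land = Raster(np.array([[1.0, np.nan], [1.0, 1.0]]), west=0.0, north=10.0, cellsize=5.0)
        grid = idw_grid([pt(0, 5.0, 5.0, 1.0)], resolution_deg=1.0,
                        buffer_km=10000.0, land_mask=land, bounds=BOUNDS)
        lats, lons = grid.cell_centers()
        for i, lat in enumerate(lats):
            for j, lon in enumerate(lons):
                on_land = not (lat > 5.0 and lon > 5.0)
                assert grid.mask[i, j] == on_land

    def test_no_points_rejected(self):
        with pytest.raises(ValueError):
            idw_grid([], bounds=BOUNDS)


class TestQuantileRangeGrid:
    def test_equal_values_give_zero(self):
        pts = [pt(i, 5.2, 5.2, 4.0) for i in range(6)]
        grid = quantile_range_grid(pts, resolution_deg=1.0, bounds=BOUNDS)
        assert grid.values[grid.mask].max() == 0.0

    def test_single_value_gives_zero(self):
        grid = quantile_range_grid([pt(0, 5.2, 5.2, 4.0)], resolution_deg=1.0, bounds=BOUNDS)
        assert grid.values[grid.mask].max() == 0.0

    def test_known_values_match_quantile_convention(self, rng):
        """q.9 − q.1 via manual linear interpolation of order statistics."""
        values = sorted(rng.uniform(0, 10, 10))
        pts = [pt(i, 5.2, 5.2, float(v)) for i, v in enumerate(values)]
        grid = quantile_range_grid(pts, resolution_deg=1.0, bounds=BOUNDS)

        def manual_quantile(sorted_vals, q):
            h = (len(sorted_vals) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        expected = manual_quantile(values, 0.9) - manual_quantile(values, 0.1)
        assert grid.values[grid.mask].max() == pytest.approx(expected, abs=1e-12)

    def test_cells_without_points_masked(self):
        grid = quantile_range_grid([pt(0, 5.2, 5.2, 4.0)], resolution_deg=1.0, bounds=BOUNDS)
        assert int(grid.mask.sum()) == 1


class TestLatitudinalProfile:
    def grid_from_values(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        mask = np.ones_like(values, dtype=bool) if mask is None else mask
        return TraitGrid(values, mask, resolution=1.0, west=0.0, north=10.0)

    def test_constant_grid(self):
        prof = latitudinal_profile(self.grid_from_values(np.full((10, 10), 2.5)), band_deg=5.0)
        assert np.allclose(prof["value"], 2.5)
        assert len(prof) == 2

    def test_identity_field_recovers_band(self):
        vals = np.repeat(np.arange(10, 0, -1)[:, None], 10, axis=1)  # row i has value 10-i
        grid = self.grid_from_values(vals)
        prof = latitudinal_profile(grid, band_deg=1.0)
        # cell-center latitude of row i is 9.5 - i, its value 10 - i
        assert np.allclose(prof["value"].to_numpy(), prof["lat_band"].to_numpy() + 0.5)

    def test_random_grid_matches_groupby(self, rng):
        vals = rng.uniform(0, 1, (10, 10))
        mask = rng.random((10, 10)) > 0.3
        grid = self.grid_from_values(vals, mask)
        prof = latitudinal_profile(grid, band_deg=2.0)
        lats, _ = grid.cell_centers()
        for _, row in prof.iterrows():
            band_lo = row["lat_band"] - 1.0
            rows = [i for i, la in enumerate(lats) if band_lo <= la < band_lo + 2.0]
            expected = vals[rows][mask[rows]].mean()
            assert row["value"] == pytest.approx(expected)

    def test_empty_grid_rejected(self):
        grid = self.grid_from_values(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError):
            latitudinal_profile(grid)


class TestCompareGrids:
    def make(self, vals, mask=None, res=1.0):
        vals = np.asarray(vals, dtype=float)
        mask = np.ones_like(vals, dtype=bool) if mask is None else mask
        return TraitGrid(vals, mask, resolution=res, west=0.0, north=10.0)

    def test_self_correlation(self, rng):
        g = self.make(rng.uniform(0, 1, (10, 10)))
        r, p, n = compare_grids(g, g)
        assert r == pytest.approx(1.0)
        assert n == 100

    def test_negated_values(self, rng):
        vals = rng.uniform(0, 1, (10, 10))
        r, _, _ = compare_grids(self.make(vals), self.make(-vals))
        assert r == pytest.approx(-1.0)

    def test_matches_bruteforce_over_joint_mask(self, rng):
        a = self.make(rng.uniform(0, 1, (8, 8)), rng.random((8, 8)) > 0.2)
        b = self.make(rng.uniform(0, 1, (8, 8)), rng.random((8, 8)) > 0.2)
        r, _, n = compare_grids(a, b)
        joint = a.mask & b.mask
        expected = np.corrcoef(a.values[joint], b.values[joint])[0, 1]
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == int(joint.sum())

    def test_resampling_constant_grid(self):
        a = self.make(np.full((10, 10), 5.0), res=1.0)
        b = TraitGrid(np.full((5, 5), 2.0), np.ones((5, 5), bool), resolution=2.0,
                      west=0.0, north=10.0)
        resampled = resample_bilinear(b, a)
        assert np.allclose(resampled.values[resampled.mask], 2.0)

    def test_too_few_joint_cells_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        a = self.make(np.ones((10, 10)), mask)
        with pytest.raises(ValueError):
            compare_grids(a, a)
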