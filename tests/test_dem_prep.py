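import datetime as dt

import numpy as np
import pytest

from marshelev.dem_prep import (
    ClassCodes,
    ElevationTile,
    bias_correct,
    build_aoi,
    mask_hydroflat,
    mosaic_chronological,
    parse_tile_date,
    prepare_dem,
    resample_to_grid,
)
from marshelev.grid import NODATA, AnalysisGrid, Raster


def make_tile(values, tile_id="t", date="2015-06-01", resolution=30.0,
              origin=(0.0, None), sentinel=None):
    values = np.asarray(values, dtype=float)
    oy = origin[1] if origin[1] is not None else values.shape[0] * resolution
    return ElevationTile(tile_id=tile_id, values=values, origin_x=origin[0],
                         origin_y=oy, resolution=resolution, date=date,
                         hydro_sentinel=sentinel)


class TestMaskHydroflat:
    def test_sentinel_cells_become_nodata(self):
        tile = make_tile([[1.0, -9999.0], [-9999.0, -9999.0]], sentinel=-9999.0)
        out = mask_hydroflat(tile)
        assert (~out.mask).sum() == 3
        assert out.values[0, 0] == 1.0

    def test_no_sentinel_cells_is_identity(self):
        tile = make_tile([[1.0, 2.0]], sentinel=-9999.0)
        np.testing.assert_array_equal(mask_hydroflat(tile).values, tile.values)

    def test_undocumented_sentinel_rejected(self):
        with pytest.raises(ValueError, match="sentinel"):
            mask_hydroflat(make_tile([[1.0]]))

    def test_masked_set_matches_scene_water_pixels(self, small_scene):
        cfg = small_scene.config
        factor = int(cfg.cell_size // cfg.tile_resolution)
        tile = small_scene.observed_tiles[0]
        masked = mask_hydroflat(tile)
        c0 = int((tile.origin_x - small_scene.grid.origin_x) / cfg.cell_size)
        n_cols = tile.values.shape[1] // factor
        water = np.kron(small_scene.water_mask[:, c0:c0 + n_cols],
                        np.ones((factor, factor), dtype=bool))
        np.testing.assert_array_equal(~masked.mask, water)


class TestResample:
    def test_constant_tile_stays_constant(self):
        grid = AnalysisGrid(0.0, 90.0, 3, 3)
        tile = make_tile(np.full((9, 9), 4.2), resolution=10.0, origin=(0.0, 90.0))
        out = resample_to_grid(tile, grid)
        np.testing.assert_allclose(out.values, 4.2)

    def test_block_mean_of_one_to_nine(self):
        grid = AnalysisGrid(0.0, 30.0, 1, 1)
        values = np.full((30, 30), NODATA)
        values[:3, :3] = np.arange(1, 10).reshape(3, 3)
        tile = make_tile(values, resolution=1.0, origin=(0.0, 30.0))
        out = resample_to_grid(tile, grid)
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_masked_sentinels_never_enter_the_mean(self):
        grid = AnalysisGrid(0.0, 30.0, 1, 1)
        values = np.full((3, 3), 2.0)
        values[1, 1] = -9999.0
        tile = make_tile(values, resolution=10.0, origin=(0.0, 30.0),
                         sentinel=-9999.0)
        out = resample_to_grid(mask_hydroflat(tile), grid)
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_disjoint_tile_rejected(self):
        grid = AnalysisGrid(0.0, 30.0, 1, 1)
        tile = make_tile([[1.0]], origin=(1000.0, 2000.0))
        with pytest.raises(ValueError, match="overlap"):
            resample_to_grid(tile, grid)

    def test_resampling_preserves_the_spatial_mean(self):
        grid = AnalysisGrid(0.0, 120.0, 4, 5)
        rng = np.random.default_rng(2)
        native = rng.normal(size=(12, 15))
        tile = make_tile(native, resolution=10.0, origin=(0.0, 120.0))
        out = resample_to_grid(tile, grid)
        assert out.values.mean() == pytest.approx(native.mean())


class TestMosaic:
    grid = AnalysisGrid(0.0, 30.0, 1, 2)

    def test_newest_tile_wins_on_overlap(self):
        t_old = make_tile([[1.0, 1.0]], tile_id="a", date="2010-01-01")
        t_new = make_tile([[2.0, 2.0]], tile_id="b", date="2015-01-01")
        out = mosaic_chronological([t_old, t_new], self.grid)
        np.testing.assert_array_equal(out.values, [[2.0, 2.0]])

    def test_nodata_falls_through_to_older_tile(self):
        t_old = make_tile([[1.0, 1.0]], tile_id="a", date="2010-01-01")
        t_new = make_tile([[NODATA, 2.0]], tile_id="b", date="2015-01-01")
        out = mosaic_chronological([t_old, t_new], self.grid)
        np.testing.assert_array_equal(out.values, [[1.0, 2.0]])

    def test_disjoint_tiles_union_unchanged(self):
        t_a = make_tile([[7.0, NODATA]], tile_id="a", date="2010-01-01")
        t_b = make_tile([[NODATA, 8.0]], tile_id="b", date="2010-06-01")
        out = mosaic_chronological([t_a, t_b], self.grid)
        np.testing.assert_array_equal(out.values, [[7.0, 8.0]])

    def test_equal_dates_break_on_tile_id(self):
        t_a = make_tile([[1.0, 1.0]], tile_id="a", date="2010-01-01")
        t_b = make_tile([[2.0, 2.0]], tile_id="b", date="2010-01-01")
        out = mosaic_chronological([t_a, t_b], self.grid)
        np.testing.assert_array_equal(out.values, [[2.0, 2.0]])

    def test_mosaicking_is_idempotent(self):
        t_a = make_tile([[1.0, NODATA]], tile_id="a", date="2010-01-01")
        t_b = make_tile([[2.0, 3.0]], tile_id="b", date="2015-01-01")
        first = mosaic_chronological([t_a, t_b], self.grid)
        again = mosaic_chronological([first, t_a, t_b], self.grid)
        np.testing.assert_array_equal(first.values, again.values)


class TestBiasCorrect:
    def test_standard_offset(self):
        tile = make_tile([[1.0]])
        assert bias_correct(tile, 0.173).values[0, 0] == pytest.approx(0.827)

    def test_zero_offset_is_identity_and_negative_inverts(self):
        tile = make_tile([[1.5, NODATA]])
        np.testing.assert_array_equal(bias_correct(tile, 0.0).values, tile.values)
        back = bias_correct(bias_correct(tile, 0.2), -0.2)
        np.testing.assert_allclose(back.values, tile.values)

    def test_nodata_untouched(self):
        tile = make_tile([[NODATA]])
        assert bias_correct(tile, 0.173).values[0, 0] == NODATA


class TestAoi:
    grid = AnalysisGrid(0.0, 30.0, 1, 4)
    codes = ClassCodes()

    def build(self, lc, p):
        lc = np.atleast_2d(np.asarray(lc, dtype=float))
        grid = AnalysisGrid(0.0, lc.shape[0] * 30.0, *lc.shape)
        return build_aoi(
            Raster(grid, lc),
            Raster(grid, np.atleast_2d(np.asarray(p, dtype=float))),
            codes=self.codes,
        )

    def test_one_percent_rule_for_palustrine(self):
        c = self.codes
        aoi = self.build([[c.palustrine, c.palustrine, c.estuarine_emergent,
                           c.open_water]],
                         [[0.005, 0.02, 0.0, 1.0]])
        assert list(aoi.include[0]) == [False, True, True, False]

    def test_estuarine_class_dominates_probability(self):
        c = self.codes
        aoi = self.build([[c.estuarine_emergent]], [[0.0]])
        assert aoi.include[0, 0]

    def test_probability_outside_unit_interval_rejected(self):
        c = self.codes
        with pytest.raises(ValueError, match="0, 1"):
            self.build([[c.palustrine]], [[1.2]])

    def test_aoi_monotone_in_probability(self):
        c = self.codes
        lc = [[c.palustrine, c.upland, c.developed, c.open_water]]
        lo = self.build(lc, [[0.005, 0.005, 0.005, 0.005]])
        hi = self.build(lc, [[0.5, 0.5, 0.5, 0.5]])
        assert (hi.include >= lo.include).all()

    def test_nwi_mask_unioned_in(self):
        c = self.codes
        aoi = build_aoi(
            Raster(self.grid, np.array([[c.upland, c.upland, c.upland,
                                         c.open_water]], dtype=float)),
            Raster(self.grid, np.zeros((1, 4))),
            codes=self.codes,
            nwi_mask=np.array([[True, False, False, True]]),
        )
        # open water stays excluded even under the NWI union
        assert list(aoi.include[0]) == [True, False, False, False]


def test_parse_tile_date_from_name_token():
    assert parse_tile_date("survey_20150601_v2") == dt.date(2015, 6, 1)
    with pytest.raises(ValueError):
        parse_tile_date("no-date-here")


def test_prepare_dem_end_to_end(small_scene):
    dem = prepare_dem(small_scene.observed_tiles, small_scene.grid, offset=0.173)
    assert dem.grid.same_as(small_scene.grid)
    # water never contributes: hydro-flattened cells end up nodata
    assert (~dem.mask[small_scene.water_mask]).all()
    land = dem.mask
    resid = dem.values[land] - small_scene.true_surface.values[land]
    # after bias correction the mean residual is near zero
    assert abs(resid.mean()) < 3 * 0.110
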