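"""Grid model: aggregation, resampling, mask algebra, differencing, totals."""

import numpy as np
import pytest

from agbcompare import (BiomassRaster, ExtentError, GridError, GridSpec,
                        MaskRaster, aggregate_mean, aggregate_mode, align_to,
                        choose_aggregation_factor, common_mask, difference,
                        resample_nearest, total_biomass)
from agbcompare.grids import CategoricalRaster

from conftest import make_raster


class TestGridSpec:
    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, -1.0, 2, 2)
        with pytest.raises(ValueError):
            GridSpec(0, 0, 100.0, 0, 2)

    def test_factor_related(self):
        a = GridSpec(0, 0, 240.0, 4, 4)
        b = GridSpec(0, 0, 480.0, 2, 2)
        c = GridSpec(0, 0, 250.0, 4, 4)
        assert a.is_factor_related(b)
        assert not a.is_factor_related(c)

    def test_cell_area(self):
        assert GridSpec(0, 0, 240.0, 1, 1).cell_area_ha == pytest.approx(5.76)


class TestAggregateMean:
    def test_factor_one_is_identity(self, small_raster):
        out = aggregate_mean(small_raster, 1)
        np.testing.assert_array_equal(out.values, small_raster.values)
        assert out.grid == small_raster.grid

    def test_window_mean(self, small_raster):
        out = aggregate_mean(small_raster, 2, min_valid_fraction=0.5)
        assert out.grid.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(2.5)
        assert out.valid[0, 0]

    def test_min_valid_fraction_invalidates_window(self):
        r = make_raster([[1, 2], [3, 4]], valid=[[0, 1], [1, 1]])
        out = aggregate_mean(r, 2, min_valid_fraction=0.8)
        assert not out.valid[0, 0]  # 3/4 < 0.8
        # partial mean still uses only the valid cells
        out2 = aggregate_mean(r, 2, min_valid_fraction=0.5)
        assert out2.valid[0, 0]
        assert out2.values[0, 0] == pytest.approx(3.0)

    def test_rejects_bad_factor(self, small_raster):
        with pytest.raises(ValueError):
            aggregate_mean(small_raster, 0)
        with pytest.raises(ValueError):
            aggregate_mean(small_raster, 1.5)
        with pytest.raises(ValueError):
            aggregate_mean(small_raster, 5)

    @pytest.mark.parametrize("seed", range(5))
    def test_conserves_total_with_full_mask(self, seed):
        rng = np.random.default_rng(seed)
        r = make_raster(rng.uniform(0, 300, (12, 12)))
        for factor in (2, 3, 4, 6):
            out = aggregate_mean(r, factor, min_valid_fraction=0.0)
            t0, a0 = total_biomass(r)
            t1, a1 = total_biomass(out)
            assert t1 == pytest.approx(t0, rel=1e-9)
            assert a1 == pytest.approx(a0, rel=1e-9)

    def test_constant_field_stays_constant(self):
        r = make_raster(np.full((9, 9), 42.0))
        for factor in (2, 3):
            out = aggregate_mean(r, factor)
            assert np.allclose(out.values[out.valid], 42.0)


class TestResampleNearest:
    def test_same_grid_identity(self, small_raster):
        out = resample_nearest(small_raster, small_raster.grid)
        np.testing.assert_array_equal(out.values, small_raster.values)

    def test_250_to_240_first_cell(self):
        src_grid = GridSpec(0.0, 0.0, 250.0, 4, 4)
        vals = np.arange(16, dtype=float).reshape(4, 4)
        r = BiomassRaster(src_grid, vals, np.ones((4, 4), bool))
        target = GridSpec(0.0, 0.0, 240.0, 4, 4)
        out = resample_nearest(r, target)
        # target cell (0,0) center (120, -120) is nearest source cell (0,0)
        assert out.values[0, 0] == vals[0, 0]

    def test_validity_propagates(self):
        r = make_raster([[5.0, 6.0], [7.0, 8.0]], valid=[[0, 1], [1, 1]])
        fine = GridSpec(0.0, 0.0, 50.0, 4, 4)
        out = resample_nearest(r, fine)
        assert not out.valid[0, 0] and not out.valid[1, 1]
        assert out.valid[0, 2]

    def test_disjoint_extent_errors(self, small_raster):
        far = GridSpec(1e7, -1e7, 100.0, 2, 2)
        with pytest.raises(ExtentError):
            resample_nearest(small_raster, far)


class TestCommonMaskAndDifference:
    def test_single_mask_identity(self, grid2):
        m = MaskRaster(grid2, [[True, False], [True, True]])
        out = common_mask([m])
        np.testing.assert_array_equal(out.valid, m.valid)

    def test_and_rule(self, grid2):
        a = MaskRaster(grid2, [[1, 1], [1, 0]])
        b = MaskRaster(grid2, [[1, 0], [1, 1]])
        out = common_mask([a, b])
        np.testing.assert_array_equal(out.valid, [[True, False], [True, False]])

    def test_grid_mismatch_errors(self, grid2):
        other = GridSpec(0, 0, 200.0, 2, 2)
        with pytest.raises(GridError):
            common_mask([MaskRaster(grid2, np.ones((2, 2), bool)),
                         MaskRaster(other, np.ones((2, 2), bool))])

    def test_difference_antisymmetric(self):
        rng = np.random.default_rng(0)
        a = make_raster(rng.uniform(0, 200, (5, 5)))
        b = make_raster(rng.uniform(0, 200, (5, 5)))
        d1, d2 = difference(a, b), difference(b, a)
        assert d1.is_difference
        np.testing.assert_allclose(d1.values, -d2.values)

    def test_difference_validity_and_values(self):
        a = make_raster([[10.0]], valid=[[1]])
        b = make_raster([[4.0]], valid=[[1]])
        assert difference(a, b).values[0, 0] == 6.0
        b_invalid = make_raster([[4.0]], valid=[[0]])
        assert not difference(a, b_invalid).valid[0, 0]


class TestTotalBiomass:
    def test_single_cell_area_arithmetic(self):
        r = make_raster([[100.0]], cell_size=240.0)
        total, area = total_biomass(r)
        assert area == pytest.approx(5.76)
        assert total == pytest.approx(576.0)

    def test_all_invalid_is_zero(self):
        r = make_raster([[100.0, 50.0]], valid=[[0, 0]])
        assert total_biomass(r) == (0.0, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        r = make_raster(rng.uniform(0, 100, (6, 6)))
        doubled = make_raster(r.values * 2)
        assert total_biomass(doubled)[0] == pytest.approx(2 * total_biomass(r)[0])


class TestAlignment:
    def test_choose_factor(self):
        assert choose_aggregation_factor(30.0, 240.0) == 8
        assert choose_aggregation_factor(93.0, 240.0) == 3
        assert choose_aggregation_factor(250.0, 240.0) == 1

    def test_align_fine_to_coarse_preserves_mean(self):
        rng = np.random.default_rng(2)
        fine = make_raster(rng.uniform(20, 200, (16, 16)), cell_size=60.0)
        target = GridSpec(0.0, 0.0, 240.0, 4, 4)
        out = align_to(fine, target)
        assert out.grid == target
        assert out.values.mean() == pytest.approx(fine.values.mean(), rel=0.01)


class TestAggregateMode:
    def test_mode_and_tie_break(self):
        codes = np.array([[1, 2], [2, 3]])
        c = CategoricalRaster(GridSpec(0, 0, 100.0, 2, 2), codes)
        out = aggregate_mode(c, 2)
        assert out.codes[0, 0] == 2
        tie = CategoricalRaster(GridSpec(0, 0, 100.0, 2, 2),
                                np.array([[1, 1], [2, 2]]))
        assert aggregate_mode(tie, 2).codes[0, 0] == 1  # tie -> smallest

    def test_never_invents_codes(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(1, 5, (12, 12))
        c = CategoricalRaster(GridSpec(0, 0, 100.0, 12, 12), codes)
        out = aggregate_mode(c, 3)
        assert set(np.unique(out.codes)) <= set(np.unique(codes))
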