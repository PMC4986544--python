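"""Map-algebra prediction, scaling chain order, ratio estimation, tiling."""

import numpy as np
import pytest

from treedensity.grids import CovariateStack, GridSpec
from treedensity.models import AveragedModel
from treedensity.predict import (
    DensitySurface,
    ScalingConstants,
    StageError,
    apply_scaling_chain,
    mean_reference_forest,
    per_pixel_scale,
    pixel_area,
    predict_per_ha,
    ratio_scale,
    tile_and_mosaic,
    truncate,
)


def intercept_model(mu, region_id=0):
    return AveragedModel(region_id=region_id, terms=("const",),
                         beta=np.array([np.log(mu)]), cov=np.zeros((1, 1)), theta=5.0)


@pytest.fixture()
def small_stack():
    g = GridSpec(8, 8, 100.0)
    rng = np.random.default_rng(3)
    return CovariateStack(grid=g, bands={
        "a": rng.standard_normal(g.shape), "b": rng.standard_normal(g.shape)})


class TestPixelArea:
    def test_published_pixel_side(self):
        ha, km2 = pixel_area(897.27)
        assert round(km2, 3) == 0.805

    @pytest.mark.parametrize("side,ha,km2", [(1000.0, 100.0, 1.0), (100.0, 1.0, 0.01)])
    def test_unit_cases(self, side, ha, km2):
        assert pixel_area(side) == pytest.approx((ha, km2))

    def test_nonpositive_side_rejected(self):
        with pytest.raises(ValueError):
            pixel_area(0.0)


class TestPredictPerHa:
    def test_intercept_only_uniform_surface(self, small_stack):
        surf = predict_per_ha(intercept_model(100.0), small_stack)
        assert np.allclose(surf.values, 100.0)
        assert surf.stage == "raw_per_ha"

    def test_single_covariate_closed_form(self, small_stack):
        model = AveragedModel(region_id=0, terms=("const", "a"),
                              beta=np.array([0.0, 1.0]), cov=np.zeros((2, 2)), theta=5.0)
        surf = predict_per_ha(model, small_stack)
        idx = np.unravel_index(np.argmin(np.abs(small_stack.band("a") - 2.0)), (8, 8))
        assert surf.values[idx] == pytest.approx(np.exp(small_stack.band("a")[idx]))

    def test_matches_brute_force_per_pixel(self, small_stack):
        model = AveragedModel(region_id=0, terms=("const", "a", "b"),
                              beta=np.array([1.0, 0.4, -0.7]), cov=np.zeros((3, 3)), theta=5.0)
        surf = predict_per_ha(model, small_stack)
        for r in range(8):
            for c in range(8):
                eta = 1.0 + 0.4 * small_stack.band("a")[r, c] - 0.7 * small_stack.band("b")[r, c]
                assert surf.values[r, c] == pytest.approx(np.exp(eta))

    def test_missing_band_named_in_error(self, small_stack):
        model = AveragedModel(region_id=0, terms=("const", "zzz"),
                              beta=np.array([0.0, 1.0]), cov=np.zeros((2, 2)), theta=5.0)
        with pytest.raises(KeyError, match="zzz"):
            predict_per_ha(model, small_stack)

    def test_mask_propagates_nan(self, small_stack):
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, 0] = True
        surf = predict_per_ha(intercept_model(50.0), small_stack, region_mask=mask)
        assert surf.values[0, 0] == pytest.approx(50.0)
        assert np.isnan(surf.values[1:, :]).all()


class TestScalingChain:
    @pytest.mark.parametrize("value,expected", [(12_000.0, 10_000.0), (500.0, 500.0), (10_000.0, 10_000.0)])
    def test_truncation_cases(self, small_stack, value, expected):
        surf = DensitySurface(np.full((8, 8), value), small_stack.grid, "raw_per_ha")
        assert truncate(surf, 10_000.0).values[0, 0] == expected

    def test_per_pixel_scale_arithmetic(self, small_stack):
        surf = DensitySurface(np.full((8, 8), 100.0), small_stack.grid, "truncated")
        area_ha = pixel_area(897.27)[0]
        scaled = per_pixel_scale(surf, area_ha)
        assert scaled.values[0, 0] == pytest.approx(8050.9, abs=0.1)
        assert per_pixel_scale(
            DensitySurface(np.full((8, 8), 77.0), small_stack.grid, "truncated"), 1.0
        ).values[0, 0] == 77.0

    def test_stage_order_enforced(self, small_stack):
        raw = DensitySurface(np.ones((8, 8)), small_stack.grid, "raw_per_ha")
        with pytest.raises(StageError):
            per_pixel_scale(raw, 1.0)  # must truncate first
        with pytest.raises(StageError):
            ratio_scale(raw, np.ones((8, 8)), 0.5)
        trunc = truncate(raw, 10.0)
        with pytest.raises(StageError):
            truncate(trunc, 10.0)

    def test_full_chain_stage_progression(self, small_stack):
        raw = predict_per_ha(intercept_model(100.0), small_stack)
        surf = apply_scaling_chain(raw, ScalingConstants(), np.full((8, 8), 0.5), 0.5)
        assert surf.stage == "forest_scaled"
        assert np.all(surf.values >= 0)


class TestRatioScale:
    def make_per_pixel(self, grid, value=1000.0):
        return DensitySurface(np.full(grid.shape, value), grid, "per_pixel")

    def test_zero_forest_means_zero_trees(self, small_stack):
        f = np.zeros((8, 8))
        scaled = ratio_scale(self.make_per_pixel(small_stack.grid), f, 0.63)
        assert np.all(scaled.values == 0.0)

    def test_pixel_at_reference_mean_unchanged(self, small_stack):
        f = np.full((8, 8), 0.63)
        scaled = ratio_scale(self.make_per_pixel(small_stack.grid), f, 0.63)
        assert np.allclose(scaled.values, 1000.0)

    def test_identical_covariates_scale_proportionally_to_forest(self, small_stack):
        f = np.full((8, 8), 0.2)
        f[0, 1] = 0.4
        scaled = ratio_scale(self.make_per_pixel(small_stack.grid), f, 0.63)
        assert scaled.values[0, 1] == 2.0 * scaled.values[0, 0]  # exact

    def test_monotone_in_forest_fraction(self, small_stack, rng):
        f = rng.uniform(0.1, 0.9, (8, 8))
        base = ratio_scale(self.make_per_pixel(small_stack.grid), f, 0.63)
        f2 = f.copy()
        f2[3, 3] += 0.05
        bumped = ratio_scale(self.make_per_pixel(small_stack.grid), f2, 0.63)
        assert bumped.values[3, 3] > base.values[3, 3]
        mask = np.ones((8, 8), bool)
        mask[3, 3] = False
        assert np.array_equal(bumped.values[mask], base.values[mask])

    def test_nonpositive_fbar_rejected(self, small_stack):
        with pytest.raises(ValueError):
            ratio_scale(self.make_per_pixel(small_stack.grid), np.ones((8, 8)), 0.0)


class TestMeanReferenceForest:
    def test_constant_forest(self, small_stack):
        import pandas as pd

        cx, cy = small_stack.grid.pixel_centers()
        plots = pd.DataFrame({"lat": cy.ravel()[:4], "lon": cx.ravel()[:4],
                              "trees_per_ha": [1, 2, 3, 4], "biome_id": [0, 0, 0, 0]})
        fbar = mean_reference_forest(plots, np.full((8, 8), 0.63), small_stack.grid)
        assert fbar[0] == pytest.approx(0.63)

    def test_two_plot_average(self, small_stack):
        import pandas as pd

        f = np.zeros((8, 8))
        f[0, 0], f[0, 1] = 0.2, 0.8
        cx, cy = small_stack.grid.pixel_centers()
        plots = pd.DataFrame({"lat": [cy[0, 0], cy[0, 1]], "lon": [cx[0, 0], cx[0, 1]],
                              "trees_per_ha": [1, 2], "biome_id": [0, 0]})
        fbar = mean_reference_forest(plots, f, small_stack.grid)
        assert fbar[0] == pytest.approx(0.5)


class TestTiling:
    def region_setup(self, n=16):
        from treedensity.synthetic import RegionMap, make_covariate_stack, make_region_map

        g = GridSpec(n, n, 100.0)
        stack = make_covariate_stack(g, 2, 2, 0.8, 0.1, seed=5)
        regions = make_region_map(g, 2, 1, seed=6)
        models = {
            rid: AveragedModel(region_id=rid, terms=("const", stack.names[rid]),
                               beta=np.array([np.log(100 + 50 * rid), 0.3]),
                               cov=np.zeros((2, 2)), theta=5.0)
            for rid in regions.biome_ids
        }
        return stack, regions, models

    def test_single_tile_equals_direct(self):
        stack, regions, models = self.region_setup()
        direct = tile_and_mosaic(stack, models, regions, tile_size=None)
        one = tile_and_mosaic(stack, models, regions, tile_size=16)
        assert np.array_equal(direct.values, one.values)

    def test_2x2_tiling_bit_identical(self):
        stack, regions, models = self.region_setup(16)
        direct = tile_and_mosaic(stack, models, regions, tile_size=None)
        tiled = tile_and_mosaic(stack, models, regions, tile_size=8)
        assert np.array_equal(direct.values, tiled.values)

    def test_tile_order_irrelevant(self):
        stack, regions, models = self.region_setup(16)
        fwd = tile_and_mosaic(stack, models, regions, tile_size=8, tile_order=[0, 1, 2, 3])
        rev = tile_and_mosaic(stack, models, regions, tile_size=8, tile_order=[3, 1, 0, 2])
        assert np.array_equal(fwd.values, rev.values)

    def test_missing_region_model_rejected(self):
        stack, regions, models = self.region_setup()
        del models[regions.biome_ids[0]]
        with pytest.raises(ValueError, match="no model"):
            tile_and_mosaic(stack, models, regions)

    def test_bad_tile_order_rejected(self):
        stack, regions, models = self.region_setup()
        with pytest.raises(ValueError, match="permutation"):
            tile_and_mosaic(stack, models, regions, tile_size=8, tile_order=[0, 0, 1, 2])
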