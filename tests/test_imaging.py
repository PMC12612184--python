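"""Tiling, preprocessing, CTCF arithmetic and nucleus counting."""

import numpy as np
import pytest

from curvchip.imaging import (
    aggregate,
    compute_ctcf,
    count_nuclei,
    otsu_mask,
    preprocess,
    quantify_tiles,
    split_tiles,
)
from curvchip.synthdata import ImageRecipe, make_image


class TestComputeCtcf:
    def test_uniform_tile_is_zero(self):
        """IntDen equals Area * mean everywhere, so CTCF vanishes."""
        tile = np.full((64, 64), 37.2)
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        assert compute_ctcf(tile, mask).ctcf == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_example(self):
        """100 px at intensity 10 on a zero background: CTCF = 1000."""
        tile = np.zeros((50, 50))
        mask = np.zeros((50, 50), bool)
        mask[:10, :10] = True
        tile[mask] = 10.0
        res = compute_ctcf(tile, mask)
        assert res.area_px == 100
        assert res.integrated_density == 1000.0
        assert res.mean_background == 0.0
        assert res.ctcf == 1000.0

    def test_constant_offset_invariance(self):
        """Adding c raises IntDen by c*Area and background mean by c: CTCF fixed."""
        rng = np.random.default_rng(7)
        tile = rng.gamma(2.0, 20.0, size=(128, 128))
        mask = tile > np.percentile(tile, 70)
        base = compute_ctcf(tile, mask).ctcf
        shifted = compute_ctcf(tile + 123.4, mask).ctcf
        assert shifted == pytest.approx(base, abs=1e-6 * abs(base))

    def test_full_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_ctcf(np.ones((8, 8)), np.ones((8, 8), bool))


class TestPreprocess:
    def test_uniform_maps_to_zero(self):
        out = preprocess(np.full((128, 128), 50.0), gaussian_sigma=0, rolling_ball_radius=15)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(3)
        img = rng.normal(100.0, 5.0, size=(128, 128))
        a = preprocess(img, gaussian_sigma=2, rolling_ball_radius=15)
        b = preprocess(img + 40.0, gaussian_sigma=2, rolling_ball_radius=15)
        assert np.allclose(a, b, atol=1e-6)

    def test_output_bounded_by_smoothed_input(self):
        rng = np.random.default_rng(4)
        img = rng.gamma(3.0, 10.0, size=(128, 128))
        out = preprocess(img, gaussian_sigma=0, rolling_ball_radius=12)
        assert np.all(out <= img + 1e-9)
        assert np.all(out >= -1e-9)

    def test_small_bright_spot_preserved(self):
        """A peak much narrower than the ball survives background removal."""
        yy, xx = np.mgrid[:128, :128]
        spot = 200.0 * np.exp(-((yy - 64) ** 2 + (xx - 64) ** 2) / (2 * 2.0**2))
        out = preprocess(spot + 20.0, gaussian_sigma=0, rolling_ball_radius=15)
        assert out.max() == pytest.approx(200.0, rel=0.05)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            preprocess(np.ones((32, 32)), rolling_ball_radius=0)


class TestSplitTiles:
    def test_exact_grid(self):
        ch = {"nuclei": np.zeros((2048, 2048))}
        ts = split_tiles(ch, pixel_size_um=2.0, region_boundaries_mm=(1.0, 2.5))
        assert len(ts.tiles) == 4

    def test_partial_tiles_dropped(self):
        ch = {"nuclei": np.zeros((3000, 3000))}
        ts = split_tiles(ch, pixel_size_um=2.0, region_boundaries_mm=(1.0, 2.5))
        assert len(ts.tiles) == 4  # floor(3000/1024) = 2 per axis

    def test_region_labels_by_center_radius(self):
        # 300x300 px at 10 um/px with 100 px tiles: tile centres at
        # 0.5, 1.5, 2.5 mm offsets from the origin corner.
        ch = {"nuclei": np.zeros((300, 300))}
        ts = split_tiles(
            ch, pixel_size_um=10.0, region_boundaries_mm=(1.0, 2.5), tile_size=100
        )
        labels = {t.origin_px: t.region for t in ts.tiles}
        assert labels[(0, 0)] == "A1"  # centre radius ~0.707 mm
        assert labels[(0, 100)] == "A2"  # ~1.58 mm
        assert labels[(200, 200)] == "A3"  # ~3.54 mm

    def test_missing_pixel_size(self):
        with pytest.raises(ValueError):
            split_tiles({"nuclei": np.zeros((2048, 2048))}, 0.0, (1.0, 2.5))

    def test_too_small_image(self):
        with pytest.raises(ValueError):
            split_tiles({"nuclei": np.zeros((100, 100))}, 2.0, (1.0, 2.5))


class TestCountNuclei:
    def test_blank_image(self):
        assert count_nuclei(np.zeros((256, 256))) == 0

    def test_separated_nuclei_counted_exactly(self):
        recipe = ImageRecipe(
            size_px=1024, n_nuclei=50, n_fibers=0, nuclei_min_separation_px=30, seed=5
        )
        channels, truth = make_image(recipe)
        assert count_nuclei(channels["nuclei"], min_distance_px=6) == len(truth["nuclei"])

    def test_overlapping_pairs_recall(self):
        """Watershed splits touching nuclei; recall stays above 90 %."""
        recipe = ImageRecipe(size_px=1024, n_nuclei=120, n_fibers=0, seed=8)
        channels, truth = make_image(recipe)
        got = count_nuclei(channels["nuclei"], min_distance_px=6)
        assert got >= 0.9 * len(truth["nuclei"])
        assert got <= 1.1 * len(truth["nuclei"])


@pytest.fixture(scope="module")
def per_tile():
    recipe = ImageRecipe(size_px=512, n_nuclei=40, n_fibers=60, seed=2)
    channels, _ = make_image(recipe)
    ts = split_tiles(
        channels, pixel_size_um=4.0, region_boundaries_mm=(0.6, 1.4), tile_size=256
    )
    return quantify_tiles(ts, marker_channel="green", min_distance_px=6)


class TestQuantifyAndAggregate:
    def test_per_tile_ctcf_identity(self, per_tile):
        """ctcf column always equals IntDen - Area * MeanBackground."""
        recomputed = (
            per_tile["integrated_density"]
            - per_tile["area_px"] * per_tile["mean_background"]
        )
        assert np.allclose(per_tile["ctcf"], recomputed)

    def test_aggregates_recompute_from_tiles(self, per_tile):
        agg = aggregate(per_tile)
        for region, sub in per_tile.groupby("region"):
            assert agg.loc[region, ("ctcf", "mean")] == pytest.approx(sub["ctcf"].mean())
            assert agg.loc[region, ("ctcf", "count")] == len(sub)
        assert agg.loc["all", ("ctcf", "mean")] == pytest.approx(per_tile["ctcf"].mean())


def test_otsu_mask_constant_image_is_empty():
    assert not otsu_mask(np.full((32, 32), 5.0)).any()
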