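"""Tissue mask chain and tiling."""

import numpy as np
import pytest

from fusemil.synthetic import SynthSlideSpec, gen_synthetic_slide, random_slide_spec
from fusemil.tissue import (TissueMask, blur_mask, build_tissue_mask,
                            extract_thumbnail, flat_mask, refine_mask,
                            remove_fat_and_dark, tile_slide)


class TestThumbnail:
    @pytest.mark.parametrize("shape,ds,expected", [
        ((2240, 2240, 3), 10, (224, 224, 3)),
        ((224, 224, 3), 1, (224, 224, 3)),
        ((224, 448, 3), 2, (112, 224, 3)),
    ])
    def test_dimension_arithmetic(self, shape, ds, expected, rng):
        img = rng.integers(0, 255, size=shape, dtype=np.uint8)
        assert extract_thumbnail(img, ds).shape == expected

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            extract_thumbnail(np.zeros((0, 0, 3), dtype=np.uint8), 2)


class TestBlurMask:
    def test_uniform_image_all_dropped(self):
        assert not blur_mask(np.full((64, 64), 128, dtype=np.uint8)).any()

    def test_zero_threshold_keeps_everything(self):
        img = np.full((32, 32), 77, dtype=np.uint8)
        assert blur_mask(img, threshold=0.0).all()

    def test_planted_blur_patch_dropped_sharp_kept(self):
        spec = SynthSlideSpec(tissue_blobs=0, tissue_rects=[(60, 60, 260, 260)],
                              blur_patches=[(100, 100, 80, 80)], seed=0)
        img, masks = gen_synthetic_slide(spec)
        keep = blur_mask(img)
        # erode truth edges: the Gaussian smoothing bleeds a few pixels
        blur_core = masks["blur"][110:170, 110:170]
        keep_core = keep[110:170, 110:170]
        assert keep_core[blur_core].mean() < 0.10
        sharp = masks["tissue"] & ~masks["blur"]
        assert (~keep[sharp]).mean() < 0.10


class TestFlatMask:
    def test_constant_background_dropped(self):
        assert not flat_mask(np.full((64, 64), 250, dtype=np.uint8)).any()

    def test_noise_kept_above_tolerance(self, rng):
        img = rng.integers(0, 255, size=(64, 64)).astype(np.uint8)
        assert flat_mask(img, flat_tol=0.02).mean() > 0.95

    def test_planted_blob_retained_background_dropped(self):
        spec = SynthSlideSpec(tissue_blobs=0, tissue_rects=[(100, 100, 150, 150)], seed=1)
        img, masks = gen_synthetic_slide(spec)
        keep = flat_mask(img)
        inner = np.zeros_like(masks["tissue"])
        inner[110:240, 110:240] = True
        assert keep[inner].mean() > 0.9
        far_bg = np.zeros_like(inner)
        far_bg[:80, :80] = True
        assert keep[far_bg].mean() < 0.05

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            flat_mask(np.zeros((8, 8)), window=4)


class TestRefineMask:
    def test_small_island_removed(self):
        m = np.zeros((16, 16), dtype=bool)
        m[5, 5] = True
        assert not refine_mask(m, min_object=10).any()

    def test_small_hole_filled(self):
        m = np.ones((16, 16), dtype=bool)
        m[7:9, 7:9] = False
        assert refine_mask(m, min_object=1, max_hole=10).all()

    def test_component_at_exact_min_object_kept(self):
        m = np.zeros((16, 16), dtype=bool)
        m[2:5, 2:5] = True          # 9-pixel component
        assert refine_mask(m, min_object=9).sum() == 9
        assert not refine_mask(m, min_object=10).any()


class TestFatDark:
    def _fixture(self):
        spec = SynthSlideSpec(
            tissue_blobs=0, tissue_rects=[(100, 100, 180, 180)],
            dark_labels=[(10, 10, 50, 26)], fat_holes=[(150, 150, 30, 30)], seed=2)
        return gen_synthetic_slide(spec)

    def test_dark_label_removed(self):
        img, masks = self._fixture()
        start = masks["dark"] | masks["tissue_raw"]
        out = remove_fat_and_dark(start, img)
        assert (out & masks["dark"]).sum() == 0

    def test_enclosed_fat_removed(self):
        img, masks = self._fixture()
        start = masks["tissue_raw"].copy()     # fat filled in, as after hole-fill
        out = remove_fat_and_dark(start, img)
        assert (out & masks["fat"]).mean() < 0.05

    def test_mid_intensity_tissue_untouched(self):
        img, masks = self._fixture()
        start = masks["tissue"] & ~masks["fat"]
        out = remove_fat_and_dark(start.copy(), img)
        assert np.array_equal(out, start)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            remove_fat_and_dark(np.ones((4, 4), dtype=bool),
                                np.zeros((5, 5), dtype=np.uint8))


class TestBuildMask:
    def test_blank_slide_empty_mask_with_log(self):
        img, _ = gen_synthetic_slide(SynthSlideSpec(tissue_blobs=0, seed=0))
        tm = build_tissue_mask(img)
        assert not tm.mask.any()
        assert [s for s, _ in tm.stage_log] == [
            "blur", "flat", "remove_small_objects", "fill_holes", "fat_dark"]

    def test_recovers_planted_tissue(self):
        img, masks = gen_synthetic_slide(random_slide_spec(0))
        tm = build_tissue_mask(img)
        jac = (tm.mask & masks["tissue"]).sum() / (tm.mask | masks["tissue"]).sum()
        assert jac >= 0.8

    def test_only_hole_filling_adds_pixels(self):
        img, _ = gen_synthetic_slide(random_slide_spec(1))
        for stage, delta in build_tissue_mask(img).stage_log:
            if stage == "fill_holes":
                assert delta >= 0
            else:
                assert delta <= 0


class TestTiling:
    def test_full_mask_tile_arithmetic(self):
        tm = TissueMask(mask=np.ones((448, 448), dtype=bool), scale=1.0)
        ts = tile_slide(tm, (448, 448), tile_size=224, coverage_min=0.5)
        assert len(ts) == 4

    def test_empty_mask_no_tiles(self):
        tm = TissueMask(mask=np.zeros((448, 448), dtype=bool), scale=1.0)
        assert len(tile_slide(tm, (448, 448))) == 0

    def test_tile_larger_than_image_is_empty_not_error(self):
        tm = TissueMask(mask=np.ones((100, 100), dtype=bool), scale=1.0)
        assert len(tile_slide(tm, (100, 100), tile_size=224)) == 0

    def test_half_covered_row_threshold(self):
        # mask covers the left half of a 224x448 strip: the right tile is
        # exactly 50% covered... construct 40% and 60% cases instead
        mask = np.zeros((224, 448), dtype=bool)
        mask[:, :224] = True
        mask[:, 224:224 + int(0.45 * 224)] = True     # right tile 45% covered
        tm = TissueMask(mask=mask, scale=1.0)
        assert len(tile_slide(tm, (448, 224), coverage_min=0.6)) == 1
        assert len(tile_slide(tm, (448, 224), coverage_min=0.4)) == 2

    def test_mask_at_coarser_scale(self):
        # thumbnail at 1/2 resolution: 112x112 mask spans a 224x224 image
        tm = TissueMask(mask=np.ones((112, 112), dtype=bool), scale=2.0)
        assert len(tile_slide(tm, (224, 224))) == 1

    def test_count_bounded_and_deterministic(self):
        img, _ = gen_synthetic_slide(random_slide_spec(3))
        tm = build_tissue_mask(img)
        ts1 = tile_slide(tm, (384, 384), tile_size=96, coverage_min=0.5)
        ts2 = tile_slide(tm, (384, 384), tile_size=96, coverage_min=0.5)
        assert np.array_equal(ts1.coords, ts2.coords)
        assert len(ts1) <= (384 // 96) ** 2

    def test_invalid_coverage_rejected(self):
        tm = TissueMask(mask=np.ones((8, 8), dtype=bool), scale=1.0)
        with pytest.raises(ValueError):
            tile_slide(tm, (8, 8), coverage_min=0.0)
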