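"""Detection pipeline stages against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mgmorph.config import PipelineConfig
from mgmorph.io import RgbImage
from mgmorph.segmentation import (GrayImage, extract_blue_channel, extract_features,
                                  fill_holes, label_objects, negative_threshold,
                                  run_detection, scale_intensity, size_filter)
from mgmorph.synthetic import generate_ihc_image

from _oracles import fill_holes_oracle, flood_fill_label


def gray(arr, stage):
    return GrayImage(pixels=np.asarray(arr, dtype=np.float64), stage=stage)


class TestBlueChannel:
    def test_selects_channel_index_2(self):
        px = np.zeros((2, 2, 3))
        px[0, 0] = (0.9, 0.5, 0.1)
        px[1, 1] = (0.0, 0.0, 1.0)
        out = extract_blue_channel(RgbImage(pixels=px))
        assert out.stage == "blue"
        assert out.pixels[0, 0] == 0.1
        assert out.pixels[1, 1] == 1.0

    def test_grayscale_replica_gives_identical_plane(self):
        plane = np.linspace(0, 1, 12).reshape(3, 4)
        img = RgbImage(pixels=np.dstack([plane] * 3))
        np.testing.assert_array_equal(extract_blue_channel(img).pixels, plane)


class TestScaleIntensity:
    def test_factor_is_exactly_numerator_at_reference_mean(self, cfg):
        const = gray(np.full((5, 5), 0.43137), "blue")
        out = scale_intensity(const, cfg)
        np.testing.assert_allclose(out.pixels, 0.43137 * 1.55, rtol=1e-12)

    def test_constant_image_arithmetic(self, cfg):
        # 0.2 * (1.55 * 0.2 / 0.43137) = 0.2 * 0.7186254 = 0.14372508
        out = scale_intensity(gray(np.full((3, 3), 0.2), "blue"), cfg)
        np.testing.assert_allclose(out.pixels, 0.2 * (1.55 * 0.2 / 0.43137), rtol=1e-12)
        assert abs(out.pixels[0, 0] - 0.14373) < 5e-6

    def test_clipping_and_degenerate_zero_image(self, cfg):
        bright = scale_intensity(gray(np.full((2, 2), 0.9), "blue"), cfg)
        assert (bright.pixels == 1.0).all()  # 0.9 * 1.55*0.9/0.43137 > 1
        dark = scale_intensity(gray(np.zeros((2, 2)), "blue"), cfg)
        assert (dark.pixels == 0.0).all()

    def test_rejects_wrong_stage(self, cfg):
        with pytest.raises(ValueError, match="blue"):
            scale_intensity(gray(np.zeros((2, 2)), "scaled"), cfg)


class TestNegativeThreshold:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.10, True),    # negative 0.90 > 0.72 -> stained foreground
         (0.50, False),   # negative 0.50
         (0.28, False)],  # negative exactly 0.72: strict inequality
    )
    def test_strict_threshold_convention(self, cfg, value, expected):
        mask = negative_threshold(gray(np.full((2, 2), value), "scaled"), cfg)
        assert mask.all() == expected and mask.any() == expected


class TestFillHoles:
    def test_ring_becomes_disk_and_idempotent(self):
        ring = np.zeros((7, 7), dtype=bool)
        ring[1:6, 1:6] = True
        ring[2:5, 2:5] = False
        filled = fill_holes(ring)
        solid = np.zeros((7, 7), dtype=bool)
        solid[1:6, 1:6] = True
        np.testing.assert_array_equal(filled, solid)
        np.testing.assert_array_equal(fill_holes(filled), filled)

    def test_open_cavity_reaching_border_unchanged(self):
        c_shape = np.zeros((7, 7), dtype=bool)
        c_shape[1:6, 1:3] = True
        c_shape[1, 1:6] = True
        c_shape[5, 1:6] = True  # cavity open to the right border
        np.testing.assert_array_equal(fill_holes(c_shape), c_shape)
        np.testing.assert_array_equal(fill_holes(c_shape), fill_holes_oracle(c_shape))

    def test_monotone_and_matches_oracle_on_random_masks(self, rng):
        for _ in range(60):
            mask = rng.random((16, 16)) < 0.45
            filled = fill_holes(mask)
            assert (filled | mask).sum() == filled.sum()  # output superset of input
            np.testing.assert_array_equal(filled, fill_holes_oracle(mask))


class TestLabelObjects:
    def test_two_squares(self, cfg):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        assert label_objects(mask, cfg).max() == 2

    def test_empty_mask(self, cfg):
        assert label_objects(np.zeros((5, 5), dtype=bool), cfg).max() == 0

    def test_diagonal_touch_depends_on_connectivity(self, cfg):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_objects(mask, cfg.replace(connectivity=8)).max() == 1
        assert label_objects(mask, cfg.replace(connectivity=4)).max() == 2

    def test_matches_flood_fill_oracle(self, cfg, rng):
        for _ in range(30):
            mask = rng.random((20, 20)) < 0.4
            for conn in (4, 8):
                ours = label_objects(mask, cfg.replace(connectivity=conn))
                np.testing.assert_array_equal(ours, flood_fill_label(mask, conn))


class TestExtractFeatures:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=np.int64)
        mask[2, 3] = 1
        f = extract_features(mask).iloc[0]
        assert f["area_px"] == 1 and f["perimeter_px"] == 1
        assert f["radius_max"] == f["radius_min"] == f["radius_sd"] == 0.0
        assert f["eccentricity"] == 0.0
        assert (f["centroid_row"], f["centroid_col"]) == (2.0, 3.0)

    def test_square_10x10(self):
        mask = np.zeros((14, 14), dtype=np.int64)
        mask[2:12, 2:12] = 1
        f = extract_features(mask).iloc[0]
        assert f["area_px"] == 100
        assert (f["centroid_row"], f["centroid_col"]) == (6.5, 6.5)
        assert f["eccentricity"] == 0.0  # mu20 == mu02, mu11 == 0 exactly
        assert f["perimeter_px"] == 36   # 100 - 8*8 interior
        # nearest boundary pixel center sits half a pixel off the axis
        np.testing.assert_allclose(f["radius_min"], np.hypot(4.5, 0.5))
        np.testing.assert_allclose(f["radius_max"], np.hypot(4.5, 4.5))

    def test_horizontal_line_1x20(self):
        mask = np.zeros((5, 24), dtype=np.int64)
        mask[2, 2:22] = 1
        f = extract_features(mask).iloc[0]
        assert f["angle"] == 0.0
        assert f["eccentricity"] > 0.99
        np.testing.assert_allclose(f["radius_max"], 9.5)
        assert f["perimeter_px"] == 20  # every pixel touches background

    def test_matches_ebimage_oracle_on_l_shape(self):
        """Frozen reference values computed independently with EBImage
        (bwlabel + computeFeatures.shape/.moment) on this exact pixel set."""
        mask = np.zeros((11, 11), dtype=np.int64)
        for x in range(2, 9):
            for y in range(3, 5):
                mask[y - 1, x - 1] = 1
        for x in range(7, 9):
            for y in range(5, 9):
                mask[y - 1, x - 1] = 1
        f = extract_features(mask).iloc[0]
        assert f["area_px"] == 22                      # s.area
        assert f["perimeter_px"] == 21                 # s.perimeter
        np.testing.assert_allclose(f["centroid_col"] + 1, 5.909090909, atol=1e-8)  # m.cx
        np.testing.assert_allclose(f["centroid_row"] + 1, 4.590909091, atol=1e-8)  # m.cy
        np.testing.assert_allclose(f["eccentricity"], 0.8430994613, atol=1e-9)     # m.ecc
        np.testing.assert_allclose(f["angle"], 0.5954015956, atol=1e-9)            # m.theta
        # EBImage measures radii to traced-contour points; conventions differ
        # by a sub-pixel offset, so agreement is approximate
        np.testing.assert_allclose(f["radius_mean"], 2.471682829, rtol=0.05)
        np.testing.assert_allclose(f["radius_max"], 4.183164617, rtol=0.05)
        np.testing.assert_allclose(f["radius_min"], 0.6353173364, rtol=0.10)

    def test_translation_invariance(self, rng):
        mask = np.zeros((40, 40), dtype=np.int64)
        blob = rng.random((8, 8)) < 0.6
        blob[3:5, 3:5] = True
        mask[2:10, 2:10] = blob
        shifted = np.zeros((40, 40), dtype=np.int64)
        shifted[15:23, 20:28] = blob
        f0 = extract_features(mask)
        f1 = extract_features(shifted)
        np.testing.assert_allclose(
            f1["centroid_row"].iloc[0] - f0["centroid_row"].iloc[0], 13, rtol=1e-12)
        np.testing.assert_allclose(
            f1["centroid_col"].iloc[0] - f0["centroid_col"].iloc[0], 18, rtol=1e-12)
        for col in ("area_px", "perimeter_px", "radius_max", "radius_min",
                    "radius_mean", "radius_sd", "eccentricity", "angle"):
            np.testing.assert_allclose(f0[col], f1[col], rtol=1e-12)

    def test_rotation_90_swaps_angle_and_preserves_shape_stats(self):
        mask = np.zeros((30, 30), dtype=np.int64)
        mask[5:9, 5:25] = 1  # 4x20 bar, angle 0
        rot = np.rot90(mask).copy()
        f0 = extract_features(mask).iloc[0]
        f1 = extract_features(rot).iloc[0]
        d = abs(f0["angle"] - f1["angle"]) % np.pi
        np.testing.assert_allclose(min(d, np.pi - d), np.pi / 2, atol=1e-9)
        for col in ("area_px", "perimeter_px", "eccentricity", "radius_max",
                    "radius_min", "radius_mean", "radius_sd"):
            np.testing.assert_allclose(f0[col], f1[col], rtol=1e-9)

    def test_empty_mask_gives_empty_table(self):
        out = extract_features(np.zeros((4, 4), dtype=np.int64))
        assert len(out) == 0 and "radius_sd" in out.columns


class TestSizeFilter:
    def test_strict_bounds(self, cfg):
        df = pd.DataFrame({"object_id": [1, 2, 3, 4], "image_id": "x",
                           "area_px": [50, 51, 2999, 3000]})
        kept = size_filter(df, cfg)
        assert sorted(kept["area_px"]) == [51, 2999]

    def test_empty_and_interior(self, cfg):
        assert len(size_filter(pd.DataFrame({"area_px": []}), cfg)) == 0
        df = pd.DataFrame({"area_px": [100]})
        assert len(size_filter(df, cfg)) == 1

    def test_all_output_areas_strictly_inside_gate(self, cfg, rng):
        df = pd.DataFrame({"area_px": rng.integers(1, 5000, size=300)})
        kept = size_filter(df, cfg)
        assert ((kept["area_px"] > 50) & (kept["area_px"] < 3000)).all()


class TestRunDetection:
    def test_pure_background_yields_empty_table(self, cfg):
        image, truth = generate_ihc_image(0, 0, 0, 0, size=(96, 96), seed=3)
        labeled, features = run_detection(image, cfg)
        assert len(truth.objects) == 0 and len(features) == 0

    def test_zero_noise_recovers_every_planted_cell(self, cfg):
        image, truth = generate_ihc_image(
            n_round=3, n_bushy=3, n_dendritic=3, n_debris=6,
            size=(512, 512), noise_sd=0.0, seed=11,
        )
        labeled, features = run_detection(image, cfg)
        planted = np.zeros_like(labeled)
        for obj in truth.objects:
            planted[obj.pixels[:, 0], obj.pixels[:, 1]] = obj.object_id
        recovered = 0
        for obj in truth.cells:
            sel = planted == obj.object_id
            hit_labels = np.unique(labeled[sel])
            hit_labels = hit_labels[hit_labels > 0]
            assert len(hit_labels) == 1
            overlap = (labeled[sel] == hit_labels[0]).mean()
            assert overlap >= 0.9
            recovered += 1
        assert recovered == 9
        assert len(features) >= 9

    def test_deterministic(self, cfg):
        image, _ = generate_ihc_image(size=(384, 384), n_debris=8, seed=5)
        l1, f1 = run_detection(image, cfg)
        l2, f2 = run_detection(image, cfg)
        np.testing.assert_array_equal(l1, l2)
        pd.testing.assert_frame_equal(f1, f2)
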