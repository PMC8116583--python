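"""Feature pool: LAB conversion, discretization, operator families."""

import numpy as np
import pytest

import oracles
from fundusiod.case_io import ValidationError
from fundusiod.feature_pool import (FIRST_ORDER_NAMES, GLCM_NAMES, GLDM_NAMES,
                                    GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES,
                                    SHAPE2D_NAMES, discretize_channel,
                                    extract_pool, first_order_features,
                                    glcm_features, glcm_matrix,
                                    lab_channels_rescaled, rgb_to_lab,
                                    roi_channel_features, shape2d_features,
                                    texture_matrix_features)
from fundusiod.roi_geometry import (MagnificationModel, build_roi_masks)
from conftest import random_level_patch

MAG = MagnificationModel(camera_constant=1.0, q=0.02, scale=0.02)


def solid(value, shape=(6, 6)):
    return np.full(shape, float(value)), np.ones(shape, dtype=bool)


class TestLab:
    def test_reference_colors(self):
        img = np.zeros((1, 3, 3), dtype=np.uint8)
        img[0, 0] = (255, 255, 255)
        img[0, 1] = (0, 0, 0)
        img[0, 2] = (119, 119, 119)
        ch = rgb_to_lab(img)
        assert ch["L"].values[0, 0] == pytest.approx(100.0, abs=0.5)
        assert ch["A"].values[0, 0] == pytest.approx(0.0, abs=0.5)
        assert ch["B"].values[0, 0] == pytest.approx(0.0, abs=0.5)
        assert ch["L"].values[0, 1] == pytest.approx(0.0, abs=0.5)
        assert ch["A"].values[0, 2] == pytest.approx(0.0, abs=0.5)
        assert ch["B"].values[0, 2] == pytest.approx(0.0, abs=0.5)

    def test_rejects_single_channel(self):
        with pytest.raises(ValidationError):
            rgb_to_lab(np.zeros((4, 4), dtype=np.uint8))

    def test_rescaled_channels_span_nominal_8bit_range(self):
        img = np.stack([np.full((2, 2), v, dtype=np.uint8)
                        for v in (255, 255, 255)], axis=-1)
        ch = lab_channels_rescaled(img)
        assert ch["L"].values[0, 0] == pytest.approx(255.0, abs=1.5)
        assert ch["A"].values[0, 0] == pytest.approx(128.0, abs=1.5)


class TestDiscretize:
    def test_hand_quantization(self):
        vals = np.array([[0.0, 24.9], [25.0, 50.0]])
        mask = np.ones((2, 2), bool)
        levels, n = discretize_channel(vals, mask, bin_width=25.0)
        assert levels.tolist() == [[1, 1], [2, 3]]
        assert n == 3

    def test_constant_region_single_level(self):
        vals, mask = solid(42.0)
        levels, n = discretize_channel(vals, mask, 25.0)
        assert n == 1 and set(levels[mask]) == {1}

    def test_refinement_never_loses_levels(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, (10, 10))
        mask = np.ones((10, 10), bool)
        for w in (40.0, 20.0, 10.0, 5.0):
            _, n_coarse = discretize_channel(vals, mask, w)
            _, n_fine = discretize_channel(vals, mask, w / 2)
            assert n_fine >= n_coarse

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            discretize_channel(*solid(1.0), bin_width=0.0)


class TestFirstOrder:
    def test_hand_computed_moments(self):
        vals = np.array([[1.0, 2.0, 3.0], [4.0, 10.0, 0.0]])
        mask = np.array([[1, 1, 1], [1, 1, 0]], dtype=bool)
        f = first_order_features(vals, mask)
        assert f["range"] == 9.0
        assert f["mean"] == 4.0
        assert f["variance"] == pytest.approx(10.0)
        assert f["skewness"] == pytest.approx(36.0 / 10.0 ** 1.5)

    def test_constant_region_degenerate_conventions(self):
        f = first_order_features(*solid(7.0))
        assert f["range"] == 0.0 and f["variance"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0
        assert f["uniformity"] == 1.0

    def test_matches_bruteforce_oracle_on_random_patches(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = rng.uniform(0, 255, (16, 16))
            mask = rng.random((16, 16)) < 0.9
            got = first_order_features(vals, mask, bin_width=25.0,
                                       pixel_area_mm2=0.04)
            want = oracles.first_order_oracle(vals, mask, 25.0, 0.04)
            for name in FIRST_ORDER_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-10,
                                                  abs=1e-10), name

    def test_rejects_singleton_mask(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            first_order_features(np.ones((3, 3)), mask)


class TestGLCM:
    def test_two_by_two_hand_example(self):
        levels = np.array([[1, 1], [2, 2]], dtype=np.int32)
        mask = np.ones((2, 2), bool)
        C = glcm_matrix(levels, mask, (0, 1))  # horizontal
        P = C / C.sum()
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        assert P[0, 1] == 0.0  # no mixed pairs -> zero contrast contribution
        assert float(((np.arange(1, 3)[:, None]
                       - np.arange(1, 3)[None, :]) ** 2 * P).sum()) == 0.0

    def test_constant_region_conventions(self):
        levels = np.ones((4, 4), dtype=np.int32)
        f = glcm_features(levels, np.ones((4, 4), bool))
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_correlation"] == 1.0

    def test_matrix_matches_skimage(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(5)
        levels = rng.integers(1, 5, (12, 12)).astype(np.int32)
        mask = np.ones((12, 12), bool)
        for off, (dist, ang) in (((0, 1), (1, 0.0)),
                                 ((1, 0), (1, np.pi / 2))):
            mine = glcm_matrix(levels, mask, off)
            ref = graycomatrix(levels.astype(np.uint8), [dist], [ang],
                               levels=5, symmetric=True)[1:, 1:, 0, 0]
            assert np.array_equal(mine, ref.astype(float))


@pytest.mark.parametrize("family,names", [
    ("GLCM", GLCM_NAMES), ("GLRLM", GLRLM_NAMES), ("GLSZM", GLSZM_NAMES),
    ("NGTDM", NGTDM_NAMES), ("GLDM", GLDM_NAMES)])
def test_texture_family_matches_bruteforce_oracle(family, names):
    """Vectorized features equal plain-loop oracles on random masked patches."""
    rng = np.random.default_rng(hash(family) % 2 ** 31)
    for _ in range(25):
        levels, mask = random_level_patch(rng)
        if family == "GLCM":
            got = glcm_features(levels, mask)
            want = oracles.glcm_features_oracle(levels, mask)
        elif family == "GLRLM":
            got = texture_matrix_features(levels, mask, family)
            want = oracles.glrlm_features_oracle(levels, mask, names)
        elif family == "GLSZM":
            got = texture_matrix_features(levels, mask, family)
            want = oracles.glszm_features_oracle(levels, mask, names)
        elif family == "NGTDM":
            got = texture_matrix_features(levels, mask, family)
            want = oracles.ngtdm_features_oracle(levels, mask)
        else:
            got = texture_matrix_features(levels, mask, family)
            want = oracles.gldm_features_oracle(levels, mask, names)
        for name in names:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


class TestTextureExamples:
    def test_single_row_run(self):
        levels = np.array([[1, 1, 1]], dtype=np.int32)
        mask = np.ones((1, 3), bool)
        from fundusiod.feature_pool import glrlm_matrix

        P = glrlm_matrix(levels, mask, (0, 1))
        assert P.shape == (1, 3) and P[0, 2] == 1.0 and P.sum() == 1.0

    def test_constant_patch_single_zone(self):
        levels = np.ones((4, 4), dtype=np.int32)
        f = texture_matrix_features(levels, np.ones((4, 4), bool), "GLSZM")
        assert f["glszm_zp"] == pytest.approx(1.0 / 16.0)  # one 16-px zone
        assert f["glszm_lae"] == pytest.approx(256.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            texture_matrix_features(np.ones((2, 2), np.int32),
                                    np.ones((2, 2), bool), "GLXX")


class TestShape2D:
    def test_circle_sphericity(self):
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (xx - 64) ** 2 + (yy - 64) ** 2 <= 50 ** 2  # r = 1 mm
        f = shape2d_features(mask, MAG)
        assert f["shape_sphericity"] == pytest.approx(1.0, abs=0.02)
        assert f["shape_mesh_surface"] == pytest.approx(np.pi, rel=0.02)

    def test_rectangle_elongation(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:50] = True  # 20 x 40 pixels
        f = shape2d_features(mask, MAG)
        assert f["shape_elongation"] == pytest.approx(0.5, rel=0.05)
        assert f["shape_major_axis"] > f["shape_minor_axis"]

    def test_dimensional_scaling(self):
        mask = np.zeros((64, 64), bool)
        mask[10:30, 10:50] = True
        f1 = shape2d_features(mask, MAG)
        mag2 = MagnificationModel(camera_constant=1.0, q=0.04, scale=0.04)
        f2 = shape2d_features(mask, mag2)
        assert f2["shape_perimeter"] == pytest.approx(
            2 * f1["shape_perimeter"], rel=1e-9)
        assert f2["shape_mesh_surface"] == pytest.approx(
            4 * f1["shape_mesh_surface"], rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            shape2d_features(np.zeros((4, 4), bool), MAG)


class TestExtractPool:
    def test_family_cardinalities(self):
        assert len(FIRST_ORDER_NAMES) == 19
        assert len(GLCM_NAMES) == 24
        assert len(GLRLM_NAMES) == 16
        assert len(GLSZM_NAMES) == 16
        assert len(NGTDM_NAMES) == 5
        assert len(GLDM_NAMES) == 14
        assert len(SHAPE2D_NAMES) == 10

    def test_roi_channel_block_has_94_features(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 255, (16, 16))
        block = roi_channel_features(vals, np.ones((16, 16), bool), 25.0, 1.0)
        assert len(block) == 94

    def test_deterministic_and_fig4_names_present(self, rendered_case):
        img, ann, mag = (rendered_case["image"], rendered_case["annotation"],
                         rendered_case["mag"])
        masks = build_roi_masks(ann, mag, img.shape[:2])
        f1, units, flags = extract_pool(img, ann, masks, mag)
        f2, _, _ = extract_pool(img, ann, masks, mag)
        assert list(f1) == list(f2)
        assert all(f1[k] == f2[k] or (np.isnan(f1[k]) and np.isnan(f2[k]))
                   for k in f1)
        for name in ("IT_L_range", "OT_A_range", "OT_B_range",
                     "OT_A_skewness", "I_B_skewness"):
            assert name in f1
        assert units["ppa_area"] == "mm^2"

    def test_locality_of_roi_features(self, rendered_case):
        img, ann, mag = (rendered_case["image"], rendered_case["annotation"],
                         rendered_case["mag"])
        masks = build_roi_masks(ann, mag, img.shape[:2])
        base, _, _ = extract_pool(img, ann, masks, mag)
        bright = img.copy()
        only_ot = masks.outer_temporal & ~masks.inner_ring
        bright[only_ot] = np.minimum(bright[only_ot] + 40, 255)
        mod, _, _ = extract_pool(bright, ann, masks, mag)
        assert mod["OT_L_mean"] != base["OT_L_mean"]
        for roi in ("D", "I", "IT"):
            assert mod[f"{roi}_L_mean"] == base[f"{roi}_L_mean"]
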