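import math

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from hamqa import texture
from hamqa.texture import (
    TextureConfig,
    cooccurrence,
    first_order_stats,
    haralick_features,
    quantize,
    rlm_features,
    run_length,
    texture_vector,
    to_grayscale,
)

from oracles import naive_glcm, naive_haralick, naive_run_lengths


class TestToGrayscale:
    @pytest.mark.parametrize(
        "color, expected",
        [((255, 255, 255), 255), ((255, 0, 0), 76), ((40, 40, 40), 40)],
    )
    def test_luma_weighting(self, color, expected):
        img = np.tile(np.array(color, dtype=np.uint8), (4, 4, 1))
        assert np.all(to_grayscale(img) == expected)

    def test_rejects_wrong_channel_count(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2), dtype=np.uint8))


class TestQuantize:
    def test_floor_binning(self):
        img = np.array([[0, 64, 128], [192, 255, 255]], dtype=np.uint8)
        assert quantize(img, 4).tolist() == [[0, 1, 2], [3, 3, 3]]

    def test_extremes_and_ordering(self):
        img = np.array([[0, 255]], dtype=np.uint8)
        q = quantize(img, 2)
        assert q.tolist() == [[0, 1]]

    def test_rejects_bad_levels(self):
        with pytest.raises(ValueError):
            quantize(np.zeros((2, 2), dtype=np.uint8), 1)


class TestFirstOrder:
    def test_constant_image_flags_undefined(self):
        mean, sd, skew, kurt = first_order_stats(np.full((5, 5), 7, dtype=np.uint8))
        assert (mean, sd) == (7.0, 0.0)
        assert math.isnan(skew) and math.isnan(kurt)

    def test_two_point_symmetric_moments(self):
        img = np.array([[0, 2], [0, 2]], dtype=np.uint8)
        mean, sd, skew, kurt = first_order_stats(img)
        assert (mean, sd, skew, kurt) == (1.0, 1.0, 0.0, 1.0)

    def test_reflection_negates_skewness(self, rng):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        m1, s1, sk1, k1 = first_order_stats(img)
        m2, s2, sk2, k2 = first_order_stats(255 - img)
        assert sk2 == pytest.approx(-sk1)
        assert s2 == pytest.approx(s1)
        assert k2 == pytest.approx(k1)

    def test_permutation_invariance(self, rng):
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        shuffled = rng.permutation(img.ravel()).reshape(img.shape)
        assert first_order_stats(img) == pytest.approx(first_order_stats(shuffled))


class TestCooccurrence:
    def test_checkerboard_horizontal(self):
        img = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        P = cooccurrence(img, levels=2, directions=(0,))
        assert P[0, 1] == P[1, 0] == 0.5
        assert P[0, 0] == P[1, 1] == 0.0

    def test_constant_image_single_cell(self):
        P = cooccurrence(np.full((4, 4), 2, dtype=np.uint8), levels=4)
        assert P[2, 2] == 1.0 and P.sum() == 1.0

    def test_normalized_and_symmetric(self, rng):
        img = rng.integers(0, 8, size=(10, 10)).astype(np.uint8)
        P = cooccurrence(img, levels=8)
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)

    def test_matches_enumeration_per_direction(self, rng):
        img = rng.integers(0, 6, size=(9, 7)).astype(np.uint8)
        offsets = {0: (0, 1), 90: (-1, 0), 45: (-1, 1), 135: (1, 1)}
        for direction, off in offsets.items():
            mine = cooccurrence(img, levels=6, directions=(direction,))
            ref = naive_glcm(img, 1, off)
            assert np.allclose(mine, ref / ref.sum())


class TestHaralick:
    def test_constant_image_degenerate_values(self):
        P = cooccurrence(np.full((4, 4), 1, dtype=np.uint8), levels=4)
        f = haralick_features(P)
        assert f["ASM"] == 1.0 and f["contrast"] == 0.0
        assert f["entropy"] == 0.0 and f["IDM"] == 1.0
        assert math.isnan(f["correlation"]) and math.isnan(f["IMC1"])

    def test_checkerboard_closed_form(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(P)
        assert f["ASM"] == pytest.approx(0.5)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_oracle_equivalence_on_random_images(self, random_images):
        for img in random_images:
            P = cooccurrence(img, levels=16)
            mine = haralick_features(P)
            ref = naive_haralick(P)
            for name in texture.HARALICK_NAMES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-8), name

    def test_overlapping_props_match_skimage(self, random_images):
        prop_map = {"ASM": "ASM", "contrast": "contrast",
                    "correlation": "correlation", "IDM": "homogeneity"}
        for img in random_images[:5]:
            glcm = graycomatrix(img, [1], [0.0], levels=16, symmetric=True, normed=True)
            mine = haralick_features(cooccurrence(img, levels=16, directions=(0,)))
            for name, prop in prop_map.items():
                assert mine[name] == pytest.approx(
                    float(graycoprops(glcm, prop)[0, 0]), abs=1e-10
                ), name

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            haralick_features(np.ones((3, 3)))


class TestRunLength:
    def test_constant_rows(self):
        R = run_length(np.full((4, 4), 3, dtype=np.uint8), 0, levels=4)
        assert R[3, 3] == 4 and R.sum() == 4

    def test_simple_row_runs(self):
        img = np.array([[0, 0, 1, 1, 1]], dtype=np.uint8)
        R = run_length(img, 0, levels=2)
        assert R[0, 1] == 1 and R[1, 2] == 1 and R.sum() == 2

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_pixel_conservation_all_directions(self, rng, direction):
        img = rng.integers(0, 5, size=(8, 11)).astype(np.uint8)
        R = run_length(img, direction, levels=5)
        lengths = np.arange(1, R.shape[1] + 1)
        assert int((R * lengths).sum()) == img.size

    def test_matches_naive_scanner(self, rng):
        img = rng.integers(0, 3, size=(6, 6)).astype(np.uint8)
        ref = naive_run_lengths(img, [row for row in img])
        R = run_length(img, 0, levels=3)
        for (g, length), count in ref.items():
            assert R[g, length - 1] == count


class TestRlmFeatures:
    def test_constant_4x4_hand_values(self):
        R = run_length(np.full((4, 4), 1, dtype=np.uint8), 0, levels=2)
        f = rlm_features(R, 16)
        assert f == {"SRE": 1 / 16, "LRE": 16.0, "GLNU": 4.0, "RLNU": 4.0, "RP": 0.25}

    def test_all_unit_runs_limit(self):
        img = np.indices((4, 4)).sum(axis=0) % 2  # checkerboard
        f = rlm_features(run_length(img.astype(np.uint8), 0, levels=2), img.size)
        assert f["SRE"] == 1.0 and f["LRE"] == 1.0 and f["RP"] == 1.0

    def test_single_gray_level_glnu_equals_total_runs(self, rng):
        img = np.zeros((5, 7), dtype=np.uint8)
        R = run_length(img, 90, levels=1)
        f = rlm_features(R, img.size)
        assert f["GLNU"] == R.sum()

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rlm_features(np.zeros((2, 2)), 4)


class TestTextureVector:
    def test_rotation_invariance_with_four_directions(self, rng):
        img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
        v1 = texture_vector(img)
        v2 = texture_vector(np.rot90(img))
        for name in texture.TEXTURE_NAMES:
            assert v1[name] == pytest.approx(v2[name], rel=1e-12), name

    def test_constant_image_flags(self):
        with pytest.warns(UserWarning, match="undefined"):
            v = texture_vector(np.full((8, 8), 100, dtype=np.uint8))
        assert v["ASM"] == 1.0 and math.isnan(v["correlation"])
        assert math.isnan(v["skewness"])

    def test_asm_falls_entropy_rises_with_noise(self, rng):
        base = np.full((48, 48), 120, dtype=np.uint8)
        asms, ents = [], []
        for frac in (0.1, 0.4, 0.8):
            img = base.copy()
            n = int(frac * img.size)
            idx = rng.choice(img.size, size=n, replace=False)
            img.ravel()[idx] = rng.integers(0, 256, size=n)
            v = texture_vector(img, warn_undefined=False)
            asms.append(v["ASM"])
            ents.append(v["entropy"])
        assert asms[0] > asms[1] > asms[2]
        assert ents[0] < ents[1] < ents[2]

    def test_rejects_tiny_images(self):
        with pytest.raises(ValueError):
            texture_vector(np.zeros((1, 5), dtype=np.uint8))
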