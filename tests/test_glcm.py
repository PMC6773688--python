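"""NA-aware symmetric co-occurrence matrices and texture statistics."""

import math

import numpy as np
import pytest

import canopyfeat as cf
from canopyfeat.glcm import (
    NA,
    EmptyGlcmError,
    compute_glcm,
    normalize_glcm,
    quantize,
    texture_features_for_transform,
    texture_stats,
)


def brute_glcm(q, d, direction, levels):
    """Exhaustive pair enumeration; counts both orders of each valid pair."""
    offsets = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}
    dr, dc = offsets[direction]
    dr, dc = dr * d, dc * d
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            i, j = q[r, c], q[r2, c2]
            if i == NA or j == NA:
                continue
            counts[i, j] += 1
            counts[j, i] += 1
    return counts


class TestQuantize:
    def test_linear_map_with_half_away_rounding(self):
        q = quantize(np.array([[0.0, 0.5], [1.0, 1.0]]))
        assert q.tolist() == [[0, 128], [255, 255]]

    def test_constant_raster_maps_to_zero(self):
        q = quantize(np.full((3, 3), 7.0))
        assert (q == 0).all()

    def test_mask_precedence(self):
        mask = np.array([[True, False], [True, True]])
        q = quantize(np.array([[0.0, 0.5], [1.0, 0.25]]), mask=mask)
        assert q[0, 1] == NA

    def test_rescale_uses_unmasked_extremes(self):
        """Quantization levels come from the full raster, not the plant region."""
        raster = np.array([[0.0, 10.0], [5.0, 5.0]])
        mask = np.array([[True, False], [True, True]])
        q = quantize(raster, mask=mask)
        assert q[0, 0] == 0
        assert q[1, 0] == 128  # 5 maps to mid-scale because the max (10) is masked


class TestComputeGlcm:
    def test_single_level_image(self):
        q = np.zeros((2, 2), dtype=np.int16)
        counts = compute_glcm(q, direction=0)
        assert counts[0, 0] == 4  # 2 pairs, each counted in both orders
        assert counts.sum() == 4

    def test_two_pixel_pair(self):
        q = np.array([[0, 1]], dtype=np.int16)
        counts = compute_glcm(q, direction=0)
        assert counts[0, 1] == 1 and counts[1, 0] == 1
        assert counts.sum() == 2

    def test_na_pairs_skipped_to_empty(self):
        q = np.array([[0, NA, 1]], dtype=np.int16)
        with pytest.raises(EmptyGlcmError):
            compute_glcm(q, direction=0)

    def test_error_carries_transform_name(self):
        q = np.full((2, 2), NA, dtype=np.int16)
        with pytest.raises(EmptyGlcmError, match="MExG"):
            compute_glcm(q, direction=0, transform="MExG")

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_matches_exhaustive_oracle(self, direction, rng):
        for _ in range(25):
            q = rng.integers(0, 8, size=rng.integers(2, 17, size=2)).astype(np.int16)
            q[rng.random(q.shape) < 0.2] = NA
            try:
                counts = compute_glcm(q, d=1, direction=direction, levels=8)
            except EmptyGlcmError:
                assert brute_glcm(q, 1, direction, 8).sum() == 0
                continue
            assert np.array_equal(counts, brute_glcm(q, 1, direction, 8))

    def test_agrees_with_skimage_on_na_free_images(self, rng):
        from skimage.feature import graycomatrix

        q = rng.integers(0, 16, size=(12, 12)).astype(np.int16)
        ours = compute_glcm(q, d=1, direction=0, levels=16)
        ref = graycomatrix(q.astype(np.uint8), [1], [0], levels=16, symmetric=True)
        assert np.array_equal(ours, ref[:, :, 0, 0])
        ours90 = compute_glcm(q, d=1, direction=90, levels=16)
        ref90 = graycomatrix(q.astype(np.uint8), [1], [np.pi / 2], levels=16, symmetric=True)
        assert np.array_equal(ours90, ref90[:, :, 0, 0])

    def test_symmetry_and_total(self, rng):
        q = rng.integers(0, 8, size=(10, 10)).astype(np.int16)
        counts = compute_glcm(q, direction=90, levels=8)
        assert np.array_equal(counts, counts.T)
        assert counts.sum() == 2 * 9 * 10  # pairs along columns


class TestNormalize:
    def test_probabilities_sum_to_one(self, rng):
        q = rng.integers(0, 8, size=(9, 9)).astype(np.int16)
        p = normalize_glcm(compute_glcm(q, direction=0, levels=8))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(p, p.T)
        # idempotent after the first application
        assert np.array_equal(normalize_glcm(p), p)

    def test_two_cell_matrix(self):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 1
        p = normalize_glcm(counts)
        assert p[0, 1] == 0.5 and p[1, 0] == 0.5


class TestTextureStats:
    def test_single_cell_degeneracy(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        s = texture_stats(p)
        assert s["MP"] == 1 and s["ASM"] == 1 and s["IDM"] == 1
        assert s["MEA"] == 0 and s["VAR"] == 0
        assert s["ENT"] == 0 and s["DIS"] == 0 and s["CON"] == 0
        assert math.isnan(s["COR"])

    def test_antidiagonal_two_cell(self):
        p = np.zeros((2, 2))
        p[0, 1] = p[1, 0] = 0.5
        s = texture_stats(p)
        assert s == pytest.approx(
            {"MP": 0.5, "MEA": 0.5, "VAR": 0.25, "COR": -1.0, "ASM": 0.5,
             "ENT": 1.0, "DIS": 1.0, "CON": 1.0, "IDM": 0.5}
        )

    def test_uniform_two_level(self):
        p = np.full((2, 2), 0.25)
        s = texture_stats(p)
        assert s["MEA"] == pytest.approx(0.5)
        assert s["VAR"] == pytest.approx(0.25)
        assert s["COR"] == pytest.approx(0.0)
        assert s["ENT"] == pytest.approx(2.0)
        assert s["ASM"] == pytest.approx(0.25)

    def test_margins_agree_for_symmetric_matrix(self, rng):
        q = rng.integers(0, 8, size=(10, 10)).astype(np.int16)
        p = normalize_glcm(compute_glcm(q, direction=0, levels=8))
        assert np.allclose(p.sum(axis=0), p.sum(axis=1))
        i = np.arange(8)
        assert np.dot(i, p.sum(axis=1)) == pytest.approx(np.dot(i, p.sum(axis=0)))

    def test_identities_on_random_matrices(self, rng):
        for _ in range(10):
            q = rng.integers(0, 8, size=(12, 12)).astype(np.int16)
            p = normalize_glcm(compute_glcm(q, direction=0, levels=8))
            s = texture_stats(p)
            assert s["CON"] >= s["DIS"] ** 2 - 1e-12  # Jensen
            assert s["ENT"] <= math.log2(np.count_nonzero(p)) + 1e-12
            assert 0 < s["ASM"] <= 1 and 0 < s["IDM"] <= 1
            assert -1 - 1e-12 <= s["COR"] <= 1 + 1e-12


class TestDirectionAveraging:
    def test_transpose_invariance(self, rng):
        """Transposing swaps the 0° and 90° matrices; averages are unchanged."""
        for _ in range(50):
            q = rng.integers(0, 8, size=rng.integers(3, 13, size=2)).astype(np.int16)
            a = texture_features_for_transform(q, levels=8)
            b = texture_features_for_transform(q.T.copy(), levels=8)
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-12, abs=1e-12)

    def test_isotropic_image_average_equals_either_direction(self):
        q = np.tile(np.array([[0, 1], [1, 0]], dtype=np.int16), (4, 4))
        avg = texture_features_for_transform(q, levels=2)
        one = cf.texture_stats(normalize_glcm(compute_glcm(q, direction=0, levels=2)))
        for k, v in one.items():
            assert avg[k] == pytest.approx(v)

    def test_315_texture_features(self, bank_and_mask):
        bank, mask = bank_and_mask
        feats = cf.all_texture_features(bank, mask)
        assert len(feats) == 315
        assert list(feats) == cf.texture_feature_names()
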