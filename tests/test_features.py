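import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phenotrack as pt
from phenotrack.features import (
    _perimeter_edges,
    cooccurrence_matrix,
)


def _instance(mask, intensity=None, frame_index=0):
    mask = np.asarray(mask, dtype=bool)
    if intensity is None:
        intensity = np.zeros(mask.shape)
    rows, cols = np.nonzero(mask)
    return pt.CellInstance(
        mask=mask,
        intensity=np.asarray(intensity, dtype=float),
        offset=(0, 0),
        centroid=(float(cols.mean()), float(rows.mean())),
        frame_index=frame_index,
    )


def _random_mask(rng, size=12):
    """Random connected blob: dilate from a seed pixel."""
    mask = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    mask[r, c] = True
    for _ in range(rng.integers(10, 40)):
        rows, cols = np.nonzero(mask)
        i = rng.integers(len(rows))
        dr, dc = rng.choice([(0, 1), (0, -1), (1, 0), (-1, 0)])
        nr, nc = int(rows[i] + dr), int(cols[i] + dc)
        if 0 <= nr < size and 0 <= nc < size:
            mask[nr, nc] = True
    return mask


class TestRegistry:
    def test_category_counts(self):
        counts = {}
        for d in pt.REGISTRY:
            counts[d.category] = counts.get(d.category, 0) + 1
        assert counts == {"size": 8, "shape": 12, "texture": 48, "movement": 1, "density": 3}

    def test_vector_alignment_and_determinism(self, square_instance):
        ctx = pt.FrameContext(image_diagonal=100.0)
        v1 = pt.extract_frame_features(square_instance, ctx)
        v2 = pt.extract_frame_features(square_instance, ctx)
        assert v1.shape == (72,)
        np.testing.assert_array_equal(v1, v2)


class TestSizeShape:
    def test_square_oracles(self, square_instance):
        f = pt.size_shape_features(square_instance)
        assert f["Area"] == 100
        assert f["Perimeter"] == 40
        assert f["AspectRatio"] == pytest.approx(1)
        assert f["Extent"] == 1
        assert f["Solidity"] == pytest.approx(1)
        assert f["Circularity"] == pytest.approx(4 * math.pi * 100 / 40**2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        mask = _random_mask(rng)
        big = np.zeros((30, 30), dtype=bool)
        big[2 : 2 + mask.shape[0], 2 : 2 + mask.shape[1]] = mask
        shifted = np.roll(big, (5, 7), axis=(0, 1))
        f1 = pt.size_shape_features(_instance(big))
        f2 = pt.size_shape_features(_instance(shifted))
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], rel=1e-9), name

    def test_rotation_90_invariance(self):
        rng = np.random.default_rng(1)
        mask = _random_mask(rng)
        f1 = pt.size_shape_features(_instance(mask))
        f2 = pt.size_shape_features(_instance(np.rot90(mask)))
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], rel=1e-8), name

    def test_area_perimeter_brute_force_oracle(self):
        # enumerate pixels and edges directly on random connected masks
        rng = np.random.default_rng(2)
        for _ in range(20):
            mask = _random_mask(rng)
            f = pt.size_shape_features(_instance(mask))
            assert f["Area"] == mask.sum()
            edges = 0
            padded = np.pad(mask, 1)
            for r in range(1, padded.shape[0] - 1):
                for c in range(1, padded.shape[1] - 1):
                    if padded[r, c]:
                        edges += sum(
                            not padded[r + dr, c + dc]
                            for dr, dc in [(0, 1), (0, -1), (1, 0), (-1, 0)]
                        )
            assert f["Perimeter"] == edges

    def test_upscaling_quadruples_area(self):
        rng = np.random.default_rng(3)
        mask = _random_mask(rng)
        doubled = np.kron(mask, np.ones((2, 2), dtype=bool))
        f1 = pt.size_shape_features(_instance(mask))
        f2 = pt.size_shape_features(_instance(doubled))
        assert f2["Area"] == 4 * f1["Area"]

    def test_single_pixel_degenerate_conventions(self):
        f = pt.size_shape_features(_instance(np.ones((1, 1), dtype=bool)))
        assert f["AspectRatio"] == 1
        assert f["Eccentricity"] == 0

    def test_empty_mask_rejected(self):
        inst = _instance(np.ones((2, 2), dtype=bool))
        inst.mask = np.zeros((2, 2), dtype=bool)
        with pytest.raises(pt.ParameterError):
            pt.size_shape_features(inst)


class TestTexture:
    def test_constant_cell_conventions(self):
        inst = _instance(np.ones((6, 6)), np.full((6, 6), 42.0))
        f = pt.texture_features(inst)
        assert f["IntensitySD_s1"] == 0
        assert f["IntensityRange_s1"] == 0
        assert f["ASM_s1"] == 1
        assert f["Contrast_s1"] == 0
        assert f["GLCMEntropy_s1"] == pytest.approx(0)

    def test_checkerboard_contrast_hand_enumerated(self):
        # horizontal/vertical offsets: every pair differs by 15 levels (225);
        # diagonal offsets pair equal values (0); equal-weight mean = 112.5
        board = (np.indices((8, 8)).sum(axis=0) % 2) * 100.0
        f = pt.texture_features(_instance(np.ones((8, 8)), board))
        assert f["Contrast_s1"] == pytest.approx(112.5)

    def test_affine_intensity_invariance_of_glcm(self):
        rng = np.random.default_rng(4)
        img = rng.normal(100, 10, (10, 10))
        mask = np.ones((10, 10))
        f1 = pt.texture_features(_instance(mask, img))
        f2 = pt.texture_features(_instance(mask, 3.5 * img + 17.0))
        for name in f1:
            if any(
                name.startswith(p)
                for p in ("ASM", "Contrast", "Correlation", "GLCMVariance",
                          "Homogeneity", "SumAverage", "SumEntropy",
                          "GLCMEntropy", "Dissimilarity", "SumVariance")
            ):
                assert f1[name] == pytest.approx(f2[name], rel=1e-9), name

    def test_cooccurrence_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            mask = _random_mask(rng)
            img = rng.normal(size=mask.shape)
            P = cooccurrence_matrix(mask, img)
            if P is not None:
                assert P.sum() == pytest.approx(1.0)

    def test_matches_skimage_on_full_rectangle(self):
        # independent oracle: single-offset GLCM on an unmasked patch
        from skimage.feature import graycomatrix, graycoprops

        rng = np.random.default_rng(6)
        img = rng.integers(0, 16, (12, 12))
        levels = np.zeros((16, 16))
        # package matrix restricted to the horizontal offset
        a = img[:, :-1].ravel()
        b = img[:, 1:].ravel()
        np.add.at(levels, (a, b), 1.0)
        np.add.at(levels, (b, a), 1.0)
        P = levels / levels.sum()
        ref = graycomatrix(img.astype(np.uint8), [1], [0], levels=16, symmetric=True, normed=True)
        np.testing.assert_allclose(P, ref[:, :, 0, 0], atol=1e-12)
        idx = np.arange(16.0)
        I, J = np.meshgrid(idx, idx, indexing="ij")
        assert (P * (I - J) ** 2).sum() == pytest.approx(
            graycoprops(ref, "contrast")[0, 0]
        )

    def test_too_few_pixels_rejected(self):
        mask = np.zeros((3, 3))
        mask[1, 1] = 1
        with pytest.raises(pt.ParameterError):
            pt.texture_features(_instance(mask))


class TestMovementDensity:
    def test_two_body_case(self):
        inst = _instance(np.ones((3, 3)))
        ctx = pt.FrameContext(other_centroids=[(31.0, 1.0)], image_diagonal=200.0)
        inst.centroid = (1.0, 1.0)
        f = pt.movement_density_features(inst, ctx)
        assert f["NeighbourCount"] == 1
        assert f["NearestNeighbourDistance"] == pytest.approx(30.0)

    def test_lone_cell_sentinel(self):
        inst = _instance(np.ones((3, 3)))
        ctx = pt.FrameContext(image_diagonal=math.sqrt(2) * 100)
        f = pt.movement_density_features(inst, ctx)
        assert f["NeighbourCount"] == 0
        assert f["NearestNeighbourDistance"] == pytest.approx(141.42, abs=0.01)

    def test_first_frame_displacement_zero(self):
        inst = _instance(np.ones((3, 3)))
        f = pt.movement_density_features(inst, pt.FrameContext())
        assert f["DisplacementFromPrev"] == 0

    def test_displacement_from_previous_centroid(self):
        inst = _instance(np.ones((3, 3)))
        inst.centroid = (3.0, 4.0)
        ctx = pt.FrameContext(prev_centroid=(0.0, 0.0))
        f = pt.movement_density_features(inst, ctx)
        assert f["DisplacementFromPrev"] == pytest.approx(5.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_frame_features_translation_invariant_property(seed):
    """All 72 features except density/movement context are unchanged when the
    mask is embedded at a different offset."""
    rng = np.random.default_rng(seed)
    mask = _random_mask(rng)
    img = rng.normal(100, 5, mask.shape)
    ctx = pt.FrameContext(image_diagonal=100.0)
    v1 = pt.extract_frame_features(_instance(mask, img), ctx)
    big_mask = np.zeros((40, 40), dtype=bool)
    big_img = np.zeros((40, 40))
    big_mask[11 : 11 + mask.shape[0], 13 : 13 + mask.shape[1]] = mask
    big_img[11 : 11 + mask.shape[0], 13 : 13 + mask.shape[1]] = img
    inst2 = pt.CellInstance.from_label(
        big_img, big_mask.astype(int), 1, frame_index=0
    )
    v2 = pt.extract_frame_features(inst2, ctx)
    np.testing.assert_allclose(v1, v2, rtol=1e-9)
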