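"""PGLCM feature extraction: pyramid, quantization, GLCM, Haralick stats."""

import numpy as np
import pandas as pd
import pytest
from skimage.feature import graycomatrix

from sarftex import (
    GLCMMatrix,
    GrayImage,
    ManifestEntry,
    PGLCMConfig,
    build_pyramid,
    compute_glcm,
    extract_dataset,
    extract_features,
    haralick_stats,
    quantize,
    rotate,
)
from sarftex.features import ANGLE_OFFSETS, feature_names, read_feature_table, write_feature_table


class TestPyramid:
    def test_ceil_halving_shapes(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(8, 8)))
        shapes = [p.pixels.shape for p in build_pyramid(img, 3)]
        assert shapes == [(8, 8), (4, 4), (2, 2)]
        odd = GrayImage(rng.integers(0, 256, size=(13, 9)))
        shapes = [p.pixels.shape for p in build_pyramid(odd, 3)]
        assert shapes == [(13, 9), (7, 5), (4, 3)]

    def test_single_level_is_input(self, tiny_image):
        assert build_pyramid(tiny_image, 1) == [tiny_image]

    def test_constant_preserved(self):
        img = GrayImage(np.full((16, 16), 77, dtype=int))
        for level in build_pyramid(img, 3):
            assert (level.pixels == 77).all()

    def test_too_small_errors_with_level(self):
        img = GrayImage(np.zeros((4, 4), dtype=int))
        with pytest.raises(ValueError, match="level 2"):
            build_pyramid(img, 3)


class TestQuantize:
    def test_identity_binning(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(4, 4)))
        assert np.array_equal(quantize(img, 256).pixels, img.pixels)

    def test_binary(self):
        img = GrayImage(np.array([[0, 255]]))
        assert quantize(img, 2).pixels.tolist() == [[0, 1]]

    def test_four_levels(self):
        img = GrayImage(np.array([[0, 100], [200, 255]]))
        q = quantize(img, 4)
        assert q.pixels.tolist() == [[0, 1], [3, 3]]
        assert q.max_level == 3

    def test_order_preserving(self, rng):
        vals = np.sort(rng.integers(0, 256, size=50))
        q = quantize(GrayImage(vals[None, :]), 16).pixels.ravel()
        assert (np.diff(q) >= 0).all()

    def test_too_few_levels(self, tiny_image):
        with pytest.raises(ValueError):
            quantize(tiny_image, 1)


def brute_force_glcm(px: np.ndarray, n_levels: int, distance: int, angle: int,
                     symmetric: bool) -> np.ndarray:
    """Oracle: enumerate every pixel pair with a double loop."""
    dr, dc = (o * distance for o in ANGLE_OFFSETS[angle])
    counts = np.zeros((n_levels, n_levels))
    h, w = px.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[px[r, c], px[r2, c2]] += 1
                if symmetric:
                    counts[px[r2, c2], px[r, c]] += 1
    return counts / counts.sum()


class TestGLCM:
    def test_constant_image_single_entry(self):
        img = GrayImage(np.full((4, 4), 2, dtype=int), max_level=3)
        g = compute_glcm(img, 1, 0)
        expected = np.zeros((4, 4))
        expected[2, 2] = 1.0
        assert np.allclose(g.probs, expected)

    def test_checkerboard_symmetric(self):
        img = GrayImage(np.array([[0, 1], [1, 0]]), max_level=1)
        g = compute_glcm(img, 1, 0, symmetric=True)
        assert np.allclose(g.probs, [[0, 0.5], [0.5, 0]])

    def test_row_asymmetric(self):
        img = GrayImage(np.array([[0, 0, 1]]), max_level=1)
        g = compute_glcm(img, 1, 0, symmetric=False)
        assert np.allclose(g.probs, [[0.5, 0.5], [0, 0]])

    def test_offset_exceeds_image(self):
        img = GrayImage(np.array([[0, 1]]), max_level=1)
        with pytest.raises(ValueError):
            compute_glcm(img, 5, 0)
        with pytest.raises(ValueError):
            compute_glcm(img, 1, 90)  # single row has no vertical pairs

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("distance", [1, 2, 3])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_brute_force_oracle(self, angle, distance, symmetric, rng):
        for _ in range(3):
            h, w = rng.integers(4, 17, size=2)
            px = rng.integers(0, 5, size=(h, w))
            img = GrayImage(px, max_level=4)
            g = compute_glcm(img, distance, angle, symmetric=symmetric)
            assert np.allclose(g.probs, brute_force_glcm(px, 5, distance, angle, symmetric))

    # skimage measures angles with the row axis growing downward, so its
    # pi/4 offset (+1, +1) is the 135-degree diagonal here and vice versa
    # (symmetric GLCMs make the offset sign itself immaterial).  Distance is
    # held at 1 because skimage rounds sin/cos offsets to integers, which
    # shortens its diagonal offsets at larger distances.
    @pytest.mark.parametrize("angle,sk_angle", [(0, 0.0), (45, 3 * np.pi / 4),
                                                (90, np.pi / 2), (135, np.pi / 4)])
    def test_skimage_cross_check_symmetric(self, angle, sk_angle, rng):
        px = rng.integers(0, 8, size=(12, 12))
        g = compute_glcm(GrayImage(px, max_level=7), 1, angle, symmetric=True)
        sk = graycomatrix(px.astype(np.uint8), [1], [sk_angle], levels=8,
                          symmetric=True, normed=True)[:, :, 0, 0]
        assert np.allclose(g.probs, sk)

    def test_normalization_and_symmetry_invariants(self, rng):
        px = rng.integers(0, 6, size=(9, 11))
        img = GrayImage(px, max_level=5)
        for angle in (0, 45, 90, 135):
            g = compute_glcm(img, 1, angle, symmetric=True)
            assert abs(g.probs.sum() - 1.0) < 1e-9
            assert np.array_equal(g.probs, g.probs.T)

    def test_rotation_maps_0deg_to_90deg(self, rng):
        px = rng.integers(0, 4, size=(8, 8))
        img = GrayImage(px, max_level=3)
        rotated = rotate(img, 1)
        g0 = compute_glcm(rotated, 1, 0, symmetric=True)
        g90 = compute_glcm(img, 1, 90, symmetric=True)
        assert np.array_equal(g0.probs, g90.probs)


class TestHaralick:
    def test_diagonal_glcm(self):
        g = GLCMMatrix(np.diag([0.5, 0.5]), 1, 0)
        s = haralick_stats(g)
        assert (s.contrast, s.homogeneity, s.energy, s.correlation) == (0, 1, 0.5, 1)

    def test_single_entry_degenerate(self):
        p = np.zeros((4, 4))
        p[1, 1] = 1.0
        s = haralick_stats(GLCMMatrix(p, 1, 0))
        assert (s.contrast, s.energy, s.homogeneity, s.correlation) == (0, 1, 1, 1)

    def test_anti_diagonal(self):
        s = haralick_stats(GLCMMatrix(np.array([[0, 0.5], [0.5, 0]]), 1, 0))
        assert (s.contrast, s.correlation, s.energy, s.homogeneity) == (1, -1, 0.5, 0.5)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            haralick_stats(GLCMMatrix(np.ones((2, 2)), 1, 0, normalized=False))
        with pytest.raises(ValueError):
            haralick_stats(GLCMMatrix(np.ones((2, 2)), 1, 0))

    def test_ranges_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            p = rng.random((n, n))
            p = (p + p.T) / (2 * p.sum())
            s = haralick_stats(GLCMMatrix(p, 1, 0))
            assert s.contrast >= 0
            assert 0 < s.energy <= 1
            assert 0 < s.homogeneity <= 1
            assert -1 - 1e-12 <= s.correlation <= 1 + 1e-12


class TestExtractFeatures:
    def test_length_formula(self, rng):
        cfg = PGLCMConfig(n_levels=3, distances=(1, 2), angles=(0, 45, 90, 135))
        img = GrayImage(rng.integers(0, 256, size=(32, 32)))
        fv = extract_features(img, cfg)
        assert len(fv) == 2 * 4 * 2 * 4 == cfg.n_features
        assert len(set(fv.names)) == len(fv.names)

    def test_constant_image_features(self):
        img = GrayImage(np.full((16, 16), 50, dtype=int))
        fv = extract_features(img, PGLCMConfig(n_levels=2, distances=(1,)))
        s = fv.as_series()
        for name, val in s.items():
            if "contrast" in name or "std" in name:
                assert val == pytest.approx(0.0, abs=1e-12), name

    def test_name_template(self):
        names = feature_names(PGLCMConfig(distances=(1, 2), angles=(0, 90)))
        assert "i=1, 0\N{DEGREE SIGN} std contrast" in names
        assert "i=2, 90\N{DEGREE SIGN} mean homogeneity" in names

    def test_deterministic(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(24, 24)))
        cfg = PGLCMConfig(n_levels=2, distances=(1,))
        assert np.array_equal(extract_features(img, cfg).values,
                              extract_features(img, cfg).values)


class TestExtractDataset:
    def test_table_shape_and_order(self, grating_entries):
        cfg = PGLCMConfig(n_levels=2, distances=(1,))
        df = extract_dataset(grating_entries, cfg)
        assert df.shape == (20, cfg.n_features + 1)
        assert tuple(df.columns[:-1]) == feature_names(cfg)
        assert df.columns[-1] == "label"

    def test_deterministic_and_csv_round_trip(self, grating_entries, tmp_path):
        cfg = PGLCMConfig(n_levels=2, distances=(1,))
        df1 = extract_dataset(grating_entries, cfg)
        df2 = extract_dataset(grating_entries, cfg)
        pd.testing.assert_frame_equal(df1, df2)
        p = tmp_path / "features.csv"
        write_feature_table(df1, p, cfg)
        back = read_feature_table(p)
        pd.testing.assert_frame_equal(back, df1)
        assert (tmp_path / "features.csv.meta").exists()

    def test_unreadable_entries_collected(self, grating_entries, tmp_path):
        bad = ManifestEntry(path=str(tmp_path / "missing.png"), label="horiz")
        cfg = PGLCMConfig(n_levels=2, distances=(1,))
        with pytest.warns(UserWarning, match="skipped"):
            df = extract_dataset([*grating_entries[:2], bad], cfg)
        assert df.shape[0] == 2
        with pytest.raises(ValueError, match="every image"):
            extract_dataset([bad], cfg)
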