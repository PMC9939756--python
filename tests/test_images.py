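"""Image I/O, grayscale conversion, and lossless augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from PIL import Image

from sarftex import (
    AugmentationSpec,
    GrayImage,
    ManifestEntry,
    balance_dataset,
    enhance,
    flip,
    load_image,
    rotate,
    save_image,
)
from sarftex.images import read_manifest, write_manifest

small_grids = arrays(
    np.int64,
    st.tuples(st.integers(1, 6), st.integers(1, 6)),
    elements=st.integers(0, 255),
)


class TestGrayImage:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GrayImage(np.array([[300]]), max_level=255)
        with pytest.raises(ValueError):
            GrayImage(np.array([[-1]]))
        with pytest.raises(ValueError):
            GrayImage(np.zeros((0, 3), dtype=int))

    def test_shape_accessors(self, tiny_image):
        assert (tiny_image.height, tiny_image.width) == (2, 2)


class TestLoadImage:
    def test_pgm_ascii_identity_read(self, tmp_path):
        p = tmp_path / "t.pgm"
        p.write_text("P2\n2 2\n255\n0 255\n255 0\n")
        img = load_image(p)
        assert img.pixels.tolist() == [[0, 255], [255, 0]]
        assert img.max_level == 255

    def test_solid_white_png(self, tmp_path):
        p = tmp_path / "w.png"
        Image.fromarray(np.full((4, 4), 255, dtype=np.uint8)).save(p)
        img = load_image(p)
        assert (img.pixels == img.max_level).all()

    def test_rgb_luminance_conversion(self, tmp_path):
        p = tmp_path / "red.png"
        Image.fromarray(np.full((2, 2, 3), (255, 0, 0), dtype=np.uint8)).save(p)
        img = load_image(p, as_gray=True)
        # ITU-R 601: round(0.299 * 255) = 76
        assert (img.pixels == 76).all()

    def test_missing_and_corrupt_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_image(tmp_path / "nope.png")
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"this is not an image")
        with pytest.raises(ValueError):
            load_image(bad)

    def test_png_round_trip(self, tmp_path, tiny_image):
        p = tmp_path / "rt.png"
        save_image(tiny_image, p)
        assert load_image(p) == tiny_image


class TestRotateFlip:
    def test_quarter_turn_ccw(self, tiny_image):
        assert rotate(tiny_image, 1).pixels.tolist() == [[2, 4], [1, 3]]

    def test_shape_transposes(self):
        img = GrayImage(np.zeros((3, 5), dtype=int))
        assert rotate(img, 1).pixels.shape == (5, 3)

    def test_unsupported_angle(self, tiny_image):
        with pytest.raises(ValueError):
            rotate(tiny_image, 5)

    def test_horizontal_flip(self, tiny_image):
        assert flip(tiny_image, "horizontal").pixels.tolist() == [[2, 1], [4, 3]]

    def test_one_by_one_unchanged(self):
        img = GrayImage(np.array([[7]]))
        assert flip(img, "vertical") == img

    def test_invalid_axis(self, tiny_image):
        with pytest.raises(ValueError):
            flip(tiny_image, "diagonal")

    @settings(max_examples=30, deadline=None)
    @given(px=small_grids, quarter=st.integers(0, 3))
    def test_four_quarter_turns_identity(self, px, quarter):
        img = GrayImage(px)
        out = img
        for _ in range(4):
            out = rotate(out, 1)
        assert out == img
        # pixel multiset preserved by any single rotation
        assert sorted(rotate(img, quarter).pixels.ravel()) == sorted(px.ravel())

    @settings(max_examples=30, deadline=None)
    @given(px=small_grids, axis=st.sampled_from(["horizontal", "vertical"]))
    def test_flip_is_involution(self, px, axis):
        img = GrayImage(px)
        assert flip(flip(img, axis), axis) == img


class TestEnhance:
    @pytest.mark.parametrize("kind", ["brightness", "color", "contrast", "sharpness"])
    def test_factor_one_is_identity(self, kind, rng):
        img = GrayImage(rng.integers(0, 256, size=(8, 8)))
        assert enhance(img, kind, 1.0) == img

    def test_brightness_scales_with_clipping(self):
        img = GrayImage(np.full((4, 4), 100, dtype=int))
        out = enhance(img, "brightness", 1.2)
        assert (out.pixels == 120).all()
        hot = GrayImage(np.full((4, 4), 240, dtype=int))
        assert enhance(hot, "brightness", 2.0).pixels.max() <= 255

    def test_contrast_fixes_uniform_image(self):
        img = GrayImage(np.full((4, 4), 77, dtype=int))
        assert enhance(img, "contrast", 1.2) == img

    def test_bad_factor_and_kind(self, tiny_image):
        with pytest.raises(ValueError):
            enhance(tiny_image, "brightness", 0.0)
        with pytest.raises(ValueError):
            enhance(tiny_image, "gamma", 1.2)

    def test_output_respects_pixel_range(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(8, 8)))
        for kind in ("brightness", "contrast", "sharpness"):
            out = enhance(img, kind, 1.7)
            assert out.pixels.min() >= 0 and out.pixels.max() <= 255


def _fake_manifest(counts: dict[str, int], rng) -> list[ManifestEntry]:
    entries = []
    for label, n in counts.items():
        for i in range(n):
            img = GrayImage(rng.integers(0, 256, size=(8, 8)))
            entries.append(ManifestEntry(path=f"{label}_{i}.png", label=label, image=img))
    return entries


class TestBalanceDataset:
    def test_already_balanced_unchanged(self, rng):
        entries = _fake_manifest({"A": 3, "B": 3}, rng)
        out = balance_dataset(entries, AugmentationSpec(), 3, seed=0)
        assert sorted(e.path for e in out) == sorted(e.path for e in entries)

    def test_deficit_filled_and_originals_kept(self, rng):
        entries = _fake_manifest({"A": 2, "B": 4}, rng)
        out = balance_dataset(entries, AugmentationSpec(), 4, seed=0)
        counts = {}
        for e in out:
            counts[e.label] = counts.get(e.label, 0) + 1
        assert counts == {"A": 4, "B": 4}
        originals = {e.path for e in entries}
        assert originals <= {e.path for e in out}
        augmented = [e for e in out if e.provenance]
        assert len(augmented) == 2 and all(e.label == "A" for e in augmented)
        assert all(e.image.pixels.min() >= 0 and e.image.pixels.max() <= 255
                   for e in augmented)

    def test_deterministic_under_seed(self, rng):
        entries = _fake_manifest({"A": 2, "B": 5}, rng)
        out1 = balance_dataset(entries, AugmentationSpec(), 5, seed=9)
        out2 = balance_dataset(entries, AugmentationSpec(), 5, seed=9)
        assert [e.path for e in out1] == [e.path for e in out2]
        assert [e.provenance for e in out1] == [e.provenance for e in out2]
        for a, b in zip(out1, out2):
            if a.image is not None:
                assert np.array_equal(a.image.pixels, b.image.pixels)

    def test_target_below_largest_class(self, rng):
        entries = _fake_manifest({"A": 2, "B": 5}, rng)
        with pytest.raises(ValueError):
            balance_dataset(entries, AugmentationSpec(), 3, seed=0)

    def test_no_operators_but_expansion_needed(self, rng):
        entries = _fake_manifest({"A": 1, "B": 2}, rng)
        empty = AugmentationSpec(rotations=(), flips=(), enhancements=())
        with pytest.raises(ValueError):
            balance_dataset(entries, empty, 2, seed=0)


class TestManifestIO:
    def test_round_trip(self, tmp_path):
        entries = [
            ManifestEntry(path=str(tmp_path / "a.png"), label="A", magnification="40X"),
            ManifestEntry(path=str(tmp_path / "b.png"), label="B",
                          provenance="rotate(1) of a.png"),
        ]
        p = tmp_path / "manifest.csv"
        write_manifest(entries, p)
        back = read_manifest(p)
        assert [(e.path, e.label, e.magnification, e.provenance) for e in back] == [
            (e.path, e.label, e.magnification, e.provenance) for e in entries
        ]

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("file,cls\nx.png,A\n")
        with pytest.raises(ValueError):
            read_manifest(p)
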