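"""Image I/O, grayscale conversion and lossless augmentation.

Images are represented as :class:`GrayImage`, a thin wrapper around a 2-D
integer array with an explicit maximum representable intensity.  The
augmentation operators are deliberately restricted to lossless transforms
(quarter-turn rotations, axis flips) plus the four Pillow enhancement kinds
(brightness, color, contrast, sharpness); arbitrary-angle rotation is out of
scope because it requires interpolation.

RGB inputs are converted to luminance with the ITU-R 601 weights
(0.299 R + 0.587 G + 0.114 B), the convention Pillow's ``convert("L")``
uses; the weights are configurable through :func:`to_grayscale`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageEnhance, UnidentifiedImageError

__all__ = [
    "GrayImage",
    "AugmentationSpec",
    "ManifestEntry",
    "load_image",
    "save_image",
    "to_grayscale",
    "rotate",
    "flip",
    "enhance",
    "balance_dataset",
    "read_manifest",
    "write_manifest",
]

#: ITU-R 601 luminance weights for RGB -> gray conversion.
LUMA_601 = (0.299, 0.587, 0.114)

ENHANCEMENT_KINDS = ("brightness", "color", "contrast", "sharpness")

_ENHANCERS = {
    "brightness": ImageEnhance.Brightness,
    "color": ImageEnhance.Color,
    "contrast": ImageEnhance.Contrast,
    "sharpness": ImageEnhance.Sharpness,
}


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of non-negative integer intensities.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Integer intensities in ``[0, max_level]``.
    max_level : int
        Maximum representable intensity (255 for 8-bit sources).
    """

    pixels: np.ndarray
    max_level: int = 255

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D grid, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixels must be integer-typed, got {px.dtype}")
        if px.min() < 0 or px.max() > self.max_level:
            raise ValueError(
                f"pixel values must lie in [0, {self.max_level}], "
                f"got range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.max_level == other.max_level and np.array_equal(self.pixels, other.pixels)


@dataclass(frozen=True)
class AugmentationSpec:
    """Catalogue of lossless/enhancement operators available for expansion.

    ``rotations`` holds quarter-turn counts (1..3; 0 is the identity and is
    never drawn), ``flips`` axis names, and ``enhancements`` pairs of
    (kind, factor) with factor > 0 — factor 1.0 is the identity for every
    kind, and 1.2 is the conventional mild-enhancement default.
    """

    rotations: tuple[int, ...] = (1, 2, 3)
    flips: tuple[str, ...] = ("horizontal", "vertical")
    enhancements: tuple[tuple[str, float], ...] = (
        ("brightness", 1.2),
        ("color", 1.2),
        ("contrast", 1.2),
        ("sharpness", 1.2),
    )

    def __post_init__(self) -> None:
        for q in self.rotations:
            if q not in (1, 2, 3):
                raise ValueError(f"rotations must be quarter-turn counts in {{1,2,3}}, got {q}")
        for ax in self.flips:
            if ax not in ("horizontal", "vertical"):
                raise ValueError(f"unknown flip axis {ax!r}")
        for kind, factor in self.enhancements:
            if kind not in ENHANCEMENT_KINDS:
                raise ValueError(f"unknown enhancement kind {kind!r}")
            if factor <= 0:
                raise ValueError(f"enhancement factor must be > 0, got {factor}")

    def operators(self) -> list[tuple[str, object]]:
        """All (op_name, parameter) pairs this spec can draw from."""
        ops: list[tuple[str, object]] = [("rotate", q) for q in self.rotations]
        ops += [("flip", ax) for ax in self.flips]
        ops += [("enhance", (kind, factor)) for kind, factor in self.enhancements]
        return ops


@dataclass
class ManifestEntry:
    """One row of a dataset manifest."""

    path: str
    label: str
    magnification: str = ""
    provenance: str = ""  # empty for originals; "<op>(<param>) of <source>" for augmented

    # in-memory image attached by balance_dataset for augmented entries
    image: GrayImage | None = field(default=None, compare=False, repr=False)


def load_image(path: str | Path, as_gray: bool = True) -> GrayImage | Image.Image:
    """Read a PNG/PGM/JPEG image.

    With ``as_gray`` (default) the result is a :class:`GrayImage`; RGB inputs
    are reduced to luminance.  With ``as_gray=False`` the Pillow image is
    returned untouched (useful for color-preserving enhancement).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        img = Image.open(path)
        img.load()
    except UnidentifiedImageError as exc:
        raise ValueError(f"unreadable or corrupt image file: {path}") from exc
    if not as_gray:
        return img
    return to_grayscale(img)


def to_grayscale(img: Image.Image | GrayImage, weights: Sequence[float] = LUMA_601) -> GrayImage:
    """Convert a Pillow image to :class:`GrayImage` via weighted luminance."""
    if isinstance(img, GrayImage):
        return img
    if img.mode in ("L", "I;16", "I"):
        arr = np.asarray(img)
        max_level = 65535 if arr.dtype.itemsize > 1 else 255
        return GrayImage(arr.astype(np.int64), max_level=max_level)
    rgb = np.asarray(img.convert("RGB"), dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    lum = rgb @ w
    return GrayImage(np.clip(np.rint(lum), 0, 255).astype(np.int64), max_level=255)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as an 8-bit PNG."""
    px = img.pixels
    if img.max_level != 255:
        px = np.rint(px * (255.0 / img.max_level)).astype(np.int64)
    Image.fromarray(px.astype(np.uint8), mode="L").save(Path(path), format="PNG")


def rotate(img: GrayImage, quarter_turns: int) -> GrayImage:
    """Rotate by a multiple of 90° counter-clockwise (lossless)."""
    if quarter_turns not in (0, 1, 2, 3):
        raise ValueError(
            f"only quarter-turn rotations are supported, got quarter_turns={quarter_turns}"
        )
    return replace(img, pixels=np.rot90(img.pixels, k=quarter_turns))


def flip(img: GrayImage, axis: str) -> GrayImage:
    """Mirror horizontally (left-right) or vertically (top-bottom)."""
    if axis == "horizontal":
        return replace(img, pixels=np.fliplr(img.pixels))
    if axis == "vertical":
        return replace(img, pixels=np.flipud(img.pixels))
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def enhance(
    img: GrayImage | Image.Image, kind: str, factor: float
) -> GrayImage | Image.Image:
    """Apply a Pillow enhancement (brightness, color, contrast, sharpness).

    Factor 1.0 is the identity for every kind.  Brightness scales
    intensities by ``factor`` with clipping; contrast interpolates between
    the image mean and the image; color interpolates from the grayscale
    version; sharpness from a smoothed version.  On grayscale input the
    color enhancer is the identity for any factor.
    """
    if kind not in _ENHANCERS:
        raise ValueError(f"unknown enhancement kind {kind!r}; expected one of {ENHANCEMENT_KINDS}")
    if factor <= 0:
        raise ValueError(f"enhancement factor must be > 0, got {factor}")
    if isinstance(img, GrayImage):
        if factor == 1.0:
            return img
        pil = Image.fromarray(img.pixels.astype(np.uint8), mode="L")
        out = _ENHANCERS[kind](pil).enhance(factor)
        return GrayImage(np.asarray(out).astype(np.int64), max_level=img.max_level)
    if factor == 1.0:
        return img
    return _ENHANCERS[kind](img).enhance(factor)


def _load_entry_image(entry: ManifestEntry) -> GrayImage:
    if entry.image is not None:
        return entry.image
    img = load_image(entry.path, as_gray=True)
    assert isinstance(img, GrayImage)
    return img


def balance_dataset(
    manifest: Sequence[ManifestEntry],
    spec: AugmentationSpec,
    target_per_class: int,
    seed: int,
) -> list[ManifestEntry]:
    """Expand every class to exactly ``target_per_class`` entries.

    Originals are always retained; the deficit is filled with augmentations
    of uniformly drawn (seeded) originals.  Augmented entries carry their
    pixels in memory and record provenance; callers persist them with
    :func:`save_image` / :func:`write_manifest`.
    """
    by_class: dict[str, list[ManifestEntry]] = {}
    for entry in manifest:
        by_class.setdefault(entry.label, []).append(entry)
    if not by_class:
        raise ValueError("manifest is empty")
    largest = max(len(v) for v in by_class.values())
    if target_per_class < largest:
        raise ValueError(
            f"target_per_class={target_per_class} is below the largest class size {largest}"
        )
    operators = spec.operators()
    needs_expansion = any(len(v) < target_per_class for v in by_class.values())
    if needs_expansion and not operators:
        raise ValueError("augmentation spec has no operators but expansion is required")

    rng = np.random.default_rng(seed)
    out: list[ManifestEntry] = []
    for label in sorted(by_class):
        entries = by_class[label]
        if not entries:
            raise ValueError(f"class {label!r} has no images")
        out.extend(entries)
        for i in range(target_per_class - len(entries)):
            src = entries[int(rng.integers(len(entries)))]
            op_name, param = operators[int(rng.integers(len(operators)))]
            img = _load_entry_image(src)
            if op_name == "rotate":
                aug = rotate(img, int(param))  # type: ignore[arg-type]
                desc = f"rotate({param})"
            elif op_name == "flip":
                aug = flip(img, str(param))
                desc = f"flip({param})"
            else:
                kind, factor = param  # type: ignore[misc]
                aug = enhance(img, kind, factor)  # type: ignore[assignment]
                desc = f"enhance({kind},{factor})"
            stem = Path(src.path).stem
            out.append(
                ManifestEntry(
                    path=f"{stem}__aug{i}_{label}.png",
                    label=label,
                    magnification=src.magnification,
                    provenance=f"{desc} of {src.path}",
                    image=aug,  # type: ignore[arg-type]
                )
            )
    return out


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Read a manifest CSV with columns path,label[,magnification][,provenance].

    Relative image paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "path" not in reader.fieldnames or "label" not in reader.fieldnames:
            raise ValueError(f"manifest {path} must have 'path' and 'label' columns")
        for row in reader:
            p = Path(row["path"])
            if not p.is_absolute():
                p = path.parent / p
            entries.append(
                ManifestEntry(
                    path=str(p),
                    label=row["label"],
                    magnification=row.get("magnification", "") or "",
                    provenance=row.get("provenance", "") or "",
                )
            )
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path) -> None:
    """Write a manifest CSV (path,label,magnification,provenance)."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "magnification", "provenance"])
        for e in entries:
            writer.writerow([e.path, e.label, e.magnification, e.provenance])
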