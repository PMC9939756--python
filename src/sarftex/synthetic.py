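"""Seeded synthetic inputs for exercising the full pipeline.

Two generators plus packaged worked-example confusion matrices:

* :func:`gen_texture_dataset` — grayscale images with class-controlled
  texture statistics.  Oriented gratings make orientation detectable by
  direction-specific co-occurrence contrast, Gaussian random fields vary
  in correlation length, and checkerboards give strong periodic structure,
  so classes are separable by GLCM features by construction.  These are
  stylized stand-ins for real histopathology or mammography texture: they
  carry no stain color, nuclei morphology, or acquisition artifacts.
* :func:`gen_tabular` — tabular features with a known informative/noise
  split for attention- and importance-recovery tests.
* :func:`published_confusion_fixtures` — published binary (8373-image),
  eight-class tumor-subtype and three-class mammogram confusion matrices,
  packaged as worked examples for the metric suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .evaluation import ConfusionMatrix
from .images import GrayImage, ManifestEntry, save_image, write_manifest

__all__ = [
    "TextureClassSpec",
    "TabularSpec",
    "gen_texture_dataset",
    "gen_tabular",
    "published_confusion_fixtures",
]

GENERATOR_KINDS = ("oriented-grating", "gaussian-random-field", "checker")


@dataclass(frozen=True)
class TextureClassSpec:
    """Recipe for one class of synthetic textured images."""

    name: str
    kind: str = "oriented-grating"
    orientation: float = 0.0  # degrees; grating wave vector direction
    period: float = 8.0  # pixels; grating period / checker block / 2x field corr. length
    amplitude: float = 80.0  # intensity contrast around mid-gray
    noise_sd: float = 10.0
    n_images: int = 10
    image_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"kind must be one of {GENERATOR_KINDS}, got {self.kind!r}")
        if self.period <= 0:
            raise ValueError(f"period must be positive, got {self.period}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        h, w = self.image_size
        if h < 4 or w < 4:
            raise ValueError(f"image_size must be at least 4x4, got {self.image_size}")


def _render(spec: TextureClassSpec, rng: np.random.Generator) -> GrayImage:
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if spec.kind == "oriented-grating":
        theta = np.deg2rad(spec.orientation)
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / spec.period + phase)
        img = 128.0 + spec.amplitude * carrier
    elif spec.kind == "gaussian-random-field":
        field = gaussian_filter(rng.standard_normal((h, w)), sigma=spec.period / 2.0,
                                mode="reflect")
        sd = field.std()
        if sd > 0:
            field = field / sd
        img = 128.0 + spec.amplitude * field
    else:  # checker
        block = max(1, int(round(spec.period)))
        phase_r = int(rng.integers(block))
        phase_c = int(rng.integers(block))
        checks = (((yy + phase_r) // block + (xx + phase_c) // block) % 2) * 2.0 - 1.0
        img = 128.0 + spec.amplitude * checks
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, size=(h, w))
    return GrayImage(np.clip(np.rint(img), 0, 255).astype(np.int64))


def gen_texture_dataset(
    specs: Sequence[TextureClassSpec],
    seed: int,
    out_dir: str | Path | None = None,
) -> list[ManifestEntry]:
    """Generate a labeled synthetic image set, optionally persisted as PNG + CSV.

    Deterministic under ``seed``.  When ``out_dir`` is given, images are
    written as PNG and a ``manifest.csv`` alongside; entries always carry
    their pixels in memory.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"class names must be distinct, got {names}")
    rng = np.random.default_rng(seed)
    entries: list[ManifestEntry] = []
    for spec in specs:
        for i in range(spec.n_images):
            img = _render(spec, rng)
            entries.append(
                ManifestEntry(path=f"{spec.name}_{i:04d}.png", label=spec.name, image=img)
            )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for e in entries:
            p = out / e.path
            save_image(e.image, p)  # type: ignore[arg-type]
            e.path = str(p)
        write_manifest(entries, out / "manifest.csv")
    return entries


@dataclass(frozen=True)
class TabularSpec:
    """Tabular benchmark with a known informative/noise feature split."""

    n_samples: int = 500
    n_informative: int = 3
    n_noise: int = 17
    n_classes: int = 2
    effect_size: float = 3.0  # class-mean separation in noise-sd units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_noise < 0:
            raise ValueError("n_noise must be >= 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class")


def gen_tabular(spec: TabularSpec) -> tuple[pd.DataFrame, np.ndarray, set[int]]:
    """Class-shifted normal informative features plus standard-normal noise.

    Informative feature values for class c are N(c * effect_size, 1); noise
    features are N(0, 1) independent of the class.  Informative columns are
    placed at seeded random positions.  Returns (features, labels,
    informative column index set).
    """
    rng = np.random.default_rng(spec.seed)
    n_feat = spec.n_informative + spec.n_noise
    y = rng.integers(0, spec.n_classes, size=spec.n_samples)
    X = rng.standard_normal((spec.n_samples, n_feat))
    positions = rng.permutation(n_feat)[: spec.n_informative]
    for j in positions:
        X[:, j] += spec.effect_size * y
    labels = np.asarray([f"c{c}" for c in y], dtype=object)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_feat)])
    return df, labels, set(int(j) for j in positions)


def published_confusion_fixtures() -> dict[str, ConfusionMatrix]:
    """Published worked-example confusion matrices for the metric suite.

    * ``breakhis_binary`` — 8373 held-out histopathology images,
      malignant vs benign.
    * ``breakhis_eight_class`` — the same test set over eight tumor
      subtypes (PC papillary, MC mucinous, LC lobular, DC ductal carcinoma;
      TA tubular adenoma, PT phyllodes tumor, F fibroadenoma, A adenosis).
    * ``mias_three_class`` — 1412 mammograms, malignant / benign / normal.
    """
    binary = ConfusionMatrix(
        counts=np.array([[3944, 186], [52, 4191]]),
        class_names=("Malignant", "Benign"),
    )
    eight = ConfusionMatrix(
        counts=np.array(
            [
                [973, 0, 0, 2, 0, 0, 0, 0],
                [4, 1035, 3, 13, 0, 2, 1, 0],
                [0, 0, 1043, 43, 0, 0, 0, 2],
                [53, 92, 121, 580, 49, 39, 67, 49],
                [0, 0, 0, 3, 1005, 0, 0, 0],
                [0, 0, 0, 0, 0, 1109, 0, 0],
                [6, 11, 9, 10, 4, 5, 981, 1],
                [0, 0, 0, 0, 0, 0, 0, 1058],
            ]
        ),
        class_names=("PC", "MC", "LC", "DC", "TA", "PT", "F", "A"),
    )
    mias = ConfusionMatrix(
        counts=np.array([[490, 0, 0], [0, 444, 0], [9, 8, 461]]),
        class_names=("Malignant", "Benign", "Normal"),
    )
    return {
        "breakhis_binary": binary,
        "breakhis_eight_class": eight,
        "mias_three_class": mias,
    }
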