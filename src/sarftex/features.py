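"""Pyramid gray-level co-occurrence (PGLCM) texture features.

The extractor builds a Gaussian pyramid for each image, quantizes every
level to a small number of gray levels, computes a gray-level co-occurrence
matrix (GLCM) for each (pyramid level, pixel distance, direction), reduces
each GLCM to four Haralick statistics — contrast, correlation, energy
(angular second moment) and homogeneity — and fuses the pyramid axis by
taking the mean and standard deviation of each statistic across levels.
The result is a named feature vector of length
``2 × 4 × |distances| × |angles|``.

Direction convention (row, column offsets for distance d):

====== ===========
angle  offset
====== ===========
0°     (0, +d)
45°    (−d, +d)
90°    (−d, 0)
135°   (−d, −d)
====== ===========

i.e. 0° pairs a pixel with its right neighbour and 90° with the pixel
above it; rows grow downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import pyramid_reduce

from .images import GrayImage, load_image, ManifestEntry

__all__ = [
    "PGLCMConfig",
    "GLCMMatrix",
    "HaralickStats",
    "FeatureVector",
    "build_pyramid",
    "quantize",
    "compute_glcm",
    "haralick_stats",
    "extract_features",
    "extract_dataset",
    "feature_names",
    "write_feature_table",
    "read_feature_table",
]

STATS = ("contrast", "correlation", "energy", "homogeneity")
AGGREGATES = ("mean", "std")

ANGLE_OFFSETS: Mapping[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class PGLCMConfig:
    """Extraction settings.

    Defaults: 3 pyramid levels, 16 gray levels, distances {1, 2, 4} and the
    four standard directions, with symmetric normalized GLCMs.
    """

    n_levels: int = 3
    quant_levels: int = 16
    distances: tuple[int, ...] = (1, 2, 4)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.quant_levels < 2:
            raise ValueError("quant_levels must be >= 2")
        if not self.distances or any(d < 1 for d in self.distances):
            raise ValueError("distances must be non-empty positive integers")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValueError(f"angle must be one of {sorted(ANGLE_OFFSETS)}, got {a}")

    @property
    def n_features(self) -> int:
        return len(AGGREGATES) * len(STATS) * len(self.distances) * len(self.angles)

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "quant_levels": self.quant_levels,
            "distances": list(self.distances),
            "angles": list(self.angles),
            "symmetric": self.symmetric,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PGLCMConfig":
        return cls(
            n_levels=int(d["n_levels"]),
            quant_levels=int(d["quant_levels"]),
            distances=tuple(int(x) for x in d["distances"]),
            angles=tuple(int(x) for x in d["angles"]),
            symmetric=bool(d["symmetric"]),
        )


@dataclass(frozen=True)
class GLCMMatrix:
    """Co-occurrence matrix for one (pyramid level, distance, angle)."""

    probs: np.ndarray  # L x L, counts or probabilities
    distance: int
    angle: int
    level: int = 0
    symmetric: bool = True
    normalized: bool = True


@dataclass(frozen=True)
class HaralickStats:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "correlation": self.correlation,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
        }


@dataclass(frozen=True)
class FeatureVector:
    """Named multi-scale texture features for one image."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def build_pyramid(img: GrayImage, n_levels: int) -> list[GrayImage]:
    """Gaussian pyramid: level 0 is the input, each next level is smoothed
    and 2x-downsampled with ceil-halving dimensions."""
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    levels = [img]
    current = img.pixels.astype(np.float64) / img.max_level
    for lev in range(1, n_levels):
        h, w = current.shape
        if (h + 1) // 2 < 2 or (w + 1) // 2 < 2:
            raise ValueError(
                f"image of shape {img.pixels.shape} is too small for pyramid level {lev} "
                f"(would be {(h + 1) // 2}x{(w + 1) // 2}, need at least 2x2)"
            )
        current = pyramid_reduce(current, downscale=2, channel_axis=None)
        px = np.clip(np.rint(current * img.max_level), 0, img.max_level).astype(np.int64)
        levels.append(GrayImage(px, max_level=img.max_level))
    return levels


def quantize(img: GrayImage, levels: int) -> GrayImage:
    """Uniformly bin intensities into ``levels`` bins; output max_level = levels - 1."""
    if levels < 2:
        raise ValueError("quantization needs at least 2 levels")
    q = (img.pixels.astype(np.int64) * levels) // (img.max_level + 1)
    return GrayImage(np.minimum(q, levels - 1), max_level=levels - 1)


def compute_glcm(
    img: GrayImage,
    distance: int,
    angle: int,
    symmetric: bool = True,
    normalize: bool = True,
    level: int = 0,
) -> GLCMMatrix:
    """Count co-occurrences of gray-level pairs at the given offset.

    The number of gray levels is ``img.max_level + 1``; quantize first to
    keep the matrix small.
    """
    if angle not in ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(ANGLE_OFFSETS)}, got {angle}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    dr, dc = (o * distance for o in ANGLE_OFFSETS[angle])
    px = img.pixels
    h, w = px.shape
    # source window such that (r+dr, c+dc) stays in bounds
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"no valid pixel pairs for distance {distance} at {angle}° on a {h}x{w} image"
        )
    i = px[r0:r1, c0:c1].ravel()
    j = px[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    n_levels = img.max_level + 1
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    if normalize:
        counts = counts / counts.sum()
    return GLCMMatrix(
        probs=counts, distance=distance, angle=angle, level=level,
        symmetric=symmetric, normalized=normalize,
    )


def haralick_stats(glcm: GLCMMatrix) -> HaralickStats:
    """Contrast, correlation, energy (ASM) and homogeneity of a normalized GLCM.

    Correlation of a degenerate matrix (zero marginal variance, e.g. a
    constant image) is defined as 1: a constant is perfectly self-correlated
    and the convention keeps features finite.
    """
    p = glcm.probs
    total = p.sum()
    if not glcm.normalized or abs(total - 1.0) > 1e-8:
        raise ValueError("haralick_stats requires a normalized GLCM (entries summing to 1)")
    n = p.shape[0]
    idx = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    diff2 = (ii - jj) ** 2
    contrast = float((p * diff2).sum())
    energy = float((p * p).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())
    px_marg = p.sum(axis=1)
    py_marg = p.sum(axis=0)
    mu_x = float(idx @ px_marg)
    mu_y = float(idx @ py_marg)
    var_x = float(((idx - mu_x) ** 2) @ px_marg)
    var_y = float(((idx - mu_y) ** 2) @ py_marg)
    denom = np.sqrt(var_x * var_y)
    if denom == 0.0:
        correlation = 1.0
    else:
        correlation = float((p * (ii - mu_x) * (jj - mu_y)).sum() / denom)
    return HaralickStats(contrast, correlation, energy, homogeneity)


def feature_names(config: PGLCMConfig) -> tuple[str, ...]:
    """Position-stable names: ``"i=<distance>, <angle>° <agg> <stat>"``."""
    names = []
    for d in config.distances:
        for a in config.angles:
            for stat in STATS:
                for agg in AGGREGATES:
                    names.append(f"i={d}, {a}\N{DEGREE SIGN} {agg} {stat}")
    return tuple(names)


def extract_features(img: GrayImage, config: PGLCMConfig = PGLCMConfig()) -> FeatureVector:
    """Extract the multi-scale fusion feature vector of one image."""
    pyramid = [quantize(level, config.quant_levels) for level in build_pyramid(img, config.n_levels)]
    values: list[float] = []
    for d in config.distances:
        for a in config.angles:
            per_level = np.array(
                [
                    list(
                        haralick_stats(
                            compute_glcm(lev_img, d, a, symmetric=config.symmetric, level=lev)
                        ).as_dict().values()
                    )
                    for lev, lev_img in enumerate(pyramid)
                ]
            )  # shape (n_levels, 4) in STATS order
            for s in range(len(STATS)):
                values.append(float(per_level[:, s].mean()))
                values.append(float(per_level[:, s].std()))
    return FeatureVector(np.asarray(values), feature_names(config))


def extract_dataset(
    manifest: Sequence[ManifestEntry],
    config: PGLCMConfig = PGLCMConfig(),
) -> pd.DataFrame:
    """Extract features for every manifest entry into a feature table.

    Returns a DataFrame whose columns are the feature names (identical order
    for every row) plus a final ``label`` column.  Per-image failures are
    collected; extraction fails only if every image fails.
    """
    names = feature_names(config)
    rows: list[np.ndarray] = []
    labels: list[str] = []
    errors: list[str] = []
    for entry in manifest:
        try:
            if entry.image is not None:
                img = entry.image
            else:
                img = load_image(entry.path, as_gray=True)  # type: ignore[assignment]
            fv = extract_features(img, config)  # type: ignore[arg-type]
            rows.append(fv.values)
            labels.append(entry.label)
        except (OSError, ValueError) as exc:
            errors.append(f"{entry.path}: {exc}")
    if not rows:
        raise ValueError("feature extraction failed for every image:\n" + "\n".join(errors))
    if errors:
        import warnings

        warnings.warn(f"{len(errors)} image(s) skipped:\n" + "\n".join(errors), stacklevel=2)
    df = pd.DataFrame(np.vstack(rows), columns=list(names))
    df["label"] = labels
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path, config: PGLCMConfig | None = None) -> None:
    """Write the feature table as CSV; config is echoed to a key-value sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        with open(path.with_suffix(path.suffix + ".meta"), "w") as fh:
            for k, v in config.to_dict().items():
                fh.write(f"{k} = {v}\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"feature table {path} has no 'label' column")
    return df
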