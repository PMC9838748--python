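"""Stage 2: visible-light homogeneity analysis of dried dye smears.

An RGB photograph of the dried smear is reduced to 8-bit gray by integer
averaging of the channels (floor((R + G + B) / 3)), contrast-stretched so
the darkest region pixel maps to 0 and the brightest to 255, and summarized
by its gray-level co-occurrence matrix (GLCM) for the horizontal
right-neighbor offset at full 256-level depth:

    contrast    = sum_ij p(i, j) * (i - j)^2
    homogeneity = sum_ij p(i, j) / (1 + |i - j|)

where p(i, j) is the probability that a pixel of level i has a right-hand
neighbor of level j.  The matrix is ordered (no symmetrization) — both
statistics depend only on |i - j|, so symmetrizing would not change them,
but the raw directional counts are preserved.  Homogeneity is 1 exactly when
every pixel equals its right neighbor, in which case contrast is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CoocMatrix",
    "TextureSummary",
    "TextureError",
    "N_GRAY_LEVELS",
    "rgb_to_gray",
    "normalize_minmax",
    "glcm_horizontal",
    "glcm_contrast",
    "glcm_homogeneity",
    "pearson",
    "analyze_dye_photo",
]

N_GRAY_LEVELS = 256


class TextureError(ValueError):
    """Invalid input to the texture pipeline."""


@dataclass(frozen=True)
class CoocMatrix:
    """Normalized co-occurrence distribution for the (0, +1) offset."""

    p: np.ndarray  # (levels, levels), rows = left pixel level
    total_pairs: int

    def __post_init__(self) -> None:
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if self.total_pairs < 1:
            raise ValueError("total_pairs must be positive")
        if np.any(self.p < 0) or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("p must be a probability distribution")

    @property
    def levels(self) -> int:
        return self.p.shape[0]


@dataclass(frozen=True)
class TextureSummary:
    contrast: float
    homogeneity: float


def _as_gray(img: np.ndarray) -> np.ndarray:
    g = np.asarray(img)
    if g.ndim != 2:
        raise TextureError("expected a 2-D gray image")
    if g.min() < 0 or g.max() > 255:
        raise TextureError("gray values must lie in [0, 255]")
    return g.astype(np.int64)


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Integer channel average: floor((R + G + B) / 3) per pixel."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise TextureError("expected an (rows, cols, 3) RGB image")
    if rgb.dtype != np.uint8:
        raise TextureError("expected 8-bit channel depth")
    return (rgb.astype(np.int64).sum(axis=2) // 3).astype(np.uint8)


def normalize_minmax(g: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Stretch gray levels so the region minimum maps to 0 and maximum to 255.

    ``v' = round((v - min) * 255 / (max - min))`` with round-half-away-from-
    zero.  When *mask* is given, the extremes are taken over the masked
    region only (pixels outside it are stretched with the same map and
    clipped).  A constant region has no defined stretch and is rejected.
    """
    g = _as_gray(g)
    region = g if mask is None else g[np.asarray(mask, dtype=bool)]
    if region.size == 0:
        raise TextureError("normalization region is empty")
    lo, hi = int(region.min()), int(region.max())
    if lo == hi:
        raise TextureError("constant image: min-max stretch is undefined")
    stretched = np.floor((g - lo) * (255.0 / (hi - lo)) + 0.5)
    return np.clip(stretched, 0, 255).astype(np.uint8)


def glcm_horizontal(
    g: np.ndarray, mask: np.ndarray | None = None, levels: int = N_GRAY_LEVELS
) -> CoocMatrix:
    """Ordered co-occurrence counts of each pixel with its right neighbor.

    With a region mask, only pairs whose two pixels are both in-region are
    counted (pairs spanning a masked-out pixel are skipped), so the region's
    row runs are enumerated exactly.
    """
    g = _as_gray(g)
    if g.shape[1] < 2:
        raise TextureError("co-occurrence needs at least two columns")
    if g.max() >= levels:
        raise TextureError(f"gray value {g.max()} outside {levels} levels")
    left, right = g[:, :-1], g[:, 1:]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != g.shape:
            raise TextureError("mask shape does not match the image")
        valid = mask[:, :-1] & mask[:, 1:]
        left, right = left[valid], right[valid]
    total = int(left.size)
    if total == 0:
        raise TextureError("no in-region horizontal neighbor pairs")
    counts = np.bincount(
        (left.ravel() * levels + right.ravel()), minlength=levels * levels
    ).reshape(levels, levels)
    return CoocMatrix(p=counts / total, total_pairs=total)


def _abs_diff(levels: int) -> np.ndarray:
    idx = np.arange(levels)
    return np.abs(idx[:, None] - idx[None, :])


def glcm_contrast(P: CoocMatrix) -> float:
    """Mean squared gray-level step between horizontal neighbors."""
    return float((P.p * _abs_diff(P.levels) ** 2).sum())


def glcm_homogeneity(P: CoocMatrix) -> float:
    """Inverse-difference statistic sum_ij p(i, j) / (1 + |i - j|)."""
    return float((P.p / (1.0 + _abs_diff(P.levels))).sum())


def pearson(x, y) -> float:
    """Sample Pearson correlation between two equally long value lists."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise TextureError("inputs must be equally long 1-D sequences")
    if x.size < 3:
        raise TextureError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TextureError("correlation is undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def analyze_dye_photo(
    image: np.ndarray, roi_mask: np.ndarray | None = None
) -> TextureSummary:
    """Full stage-2 chain on one smear photo.

    Accepts an RGB photo (converted to gray first) or an already-gray image;
    the region is contrast-stretched to the full 0–255 range and the two
    co-occurrence statistics are computed over its horizontal pairs.
    """
    img = np.asarray(image)
    gray = rgb_to_gray(img) if img.ndim == 3 else _as_gray(img).astype(np.uint8)
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if not roi_mask.any():
            raise TextureError("ROI mask selects no pixels")
    norm = normalize_minmax(gray, mask=roi_mask)
    P = glcm_horizontal(norm, mask=roi_mask)
    return TextureSummary(contrast=glcm_contrast(P), homogeneity=glcm_homogeneity(P))
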