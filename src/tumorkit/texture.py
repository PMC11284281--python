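"""Spatial gray-level dependence matrix (SGLDM/GLCM) texture features.

The co-occurrence matrix P(i, j | D, theta) counts pixel pairs at
displacement (D, theta) whose quantized gray levels are (i, j).  Over a
region of interest, a pair contributes only if *both* endpoints lie
inside the ROI, so boundary pixels never mix tumor and background
statistics.  After normalization (division by the total pair count) five
scalar statistics summarize the distribution:

    contrast        C = sum p(i,j) (i-j)^2
    dissimilarity   K = sum p(i,j) |i-j|
    homogeneity     H = sum p(i,j) / (1 + (i-j)^2)
    energy          E = sum p(i,j)^2            (angular second moment)
    correlation     L = sum p(i,j)(i-mu_i)(j-mu_j) / (sigma_i sigma_j)

plus Shannon entropy  -sum p ln p  as an auxiliary field.  Correlation of
a zero-variance (constant-ROI) matrix is defined as 1 with a degeneracy
flag: a constant region is perfectly linearly dependent by convention.

Angle offsets follow the usual image convention with row 0 at the top:
0 deg -> (0, +D), 45 deg -> (-D, +D), 90 deg -> (-D, 0), 135 deg -> (-D, -D).
Features computed for several angles are averaged arithmetically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .image_io import Image, UNIT

__all__ = [
    "GLCMConfig",
    "GLCMatrix",
    "TextureFeatures",
    "ANGLE_OFFSETS",
    "quantize",
    "compute_glcm",
    "normalize_glcm",
    "glcm_features",
    "extract_features",
    "features_to_row",
    "FEATURE_COLUMNS",
]

#: (row, col) displacement per angle, for distance D multiply by D
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

#: CSV column order for feature tables
FEATURE_COLUMNS = ["contrast", "dissimilarity", "homogeneity", "energy",
                   "correlation", "entropy"]

#: quantized level marking pixels outside the ROI
IGNORED = -1


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 32
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if not self.angles:
            raise ValueError("angles must be nonempty")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValueError(f"unsupported angle {a}; choose from 0/45/90/135")


@dataclass(frozen=True)
class GLCMatrix:
    counts: np.ndarray        # (L, L) nonnegative ints
    probabilities: np.ndarray  # (L, L) reals summing to 1 (or all 0 if degenerate)
    config: GLCMConfig
    angle: int
    n_pairs: int
    degenerate: bool = False   # True when no valid pair exists


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    correlation: float
    entropy: float
    correlation_degenerate: bool = False


def quantize(image: Image, levels: int,
             mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Uniformly bin unit intensities into ``levels`` gray levels.

    Returns an integer grid where in-ROI pixels carry their level in
    [0, levels) (intensity 1.0 maps to levels-1) and out-of-ROI pixels
    are flagged :data:`IGNORED`.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if image.value_range != UNIT:
        raise ValueError("quantize expects a unit-range image")
    grid = np.minimum((image.pixels * levels).astype(np.int64), levels - 1)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape must match image shape")
        grid = np.where(mask, grid, IGNORED)
    return grid


def compute_glcm(level_grid: np.ndarray, config: GLCMConfig,
                 angle: int) -> GLCMatrix:
    """Count co-occurring level pairs at the given angle and distance.

    Pixels flagged :data:`IGNORED` never contribute; a pair counts only
    when both endpoints are valid.  With ``symmetric`` each pair counts
    in both orders.  A grid too small to contain any pair yields a
    degenerate (n_pairs = 0) matrix rather than an error.
    """
    grid = np.asarray(level_grid)
    L = config.levels
    if grid[grid != IGNORED].size and grid.max() >= L:
        raise ValueError("level index >= configured number of levels")
    dr, dc = (config.distance * o for o in ANGLE_OFFSETS[angle])
    h, w = grid.shape

    counts = np.zeros((L, L), dtype=np.int64)
    # source window and displaced window
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 > r0 and c1 > c0:
        src = grid[r0:r1, c0:c1]
        dst = grid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = (src != IGNORED) & (dst != IGNORED)
        i, j = src[valid], dst[valid]
        np.add.at(counts, (i, j), 1)
        if config.symmetric:
            np.add.at(counts, (j, i), 1)
    n_pairs = int(counts.sum())
    glcm = GLCMatrix(counts=counts, probabilities=np.zeros((L, L)),
                     config=config, angle=angle, n_pairs=n_pairs,
                     degenerate=n_pairs == 0)
    return normalize_glcm(glcm)


def normalize_glcm(glcm: GLCMatrix) -> GLCMatrix:
    """Divide each entry by the total pair count."""
    if glcm.n_pairs == 0:
        probs = np.zeros_like(glcm.counts, dtype=np.float64)
        return GLCMatrix(glcm.counts, probs, glcm.config, glcm.angle, 0, True)
    probs = glcm.counts / glcm.n_pairs
    return GLCMatrix(glcm.counts, probs, glcm.config, glcm.angle,
                     glcm.n_pairs, False)


def glcm_features(glcm: GLCMatrix) -> TextureFeatures:
    """The five co-occurrence statistics plus entropy, from one matrix."""
    if glcm.degenerate:
        raise ValueError("cannot compute features of a degenerate (empty) GLCM")
    p = glcm.probabilities
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j

    contrast = float((p * diff ** 2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff ** 2)).sum())
    energy = float((p ** 2).sum())

    pi = p.sum(axis=1)          # marginal over rows
    pj = p.sum(axis=0)
    mu_i = float((np.arange(L) * pi).sum())
    mu_j = float((np.arange(L) * pj).sum())
    var_i = float(((np.arange(L) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(L) - mu_j) ** 2 * pj).sum())
    degenerate_corr = var_i <= 0 or var_j <= 0
    if degenerate_corr:
        correlation = 1.0
    else:
        correlation = float(
            (p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))

    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    return TextureFeatures(contrast, dissimilarity, homogeneity, energy,
                           correlation, entropy, degenerate_corr)


def extract_features(image: Image, mask: Optional[np.ndarray] = None,
                     config: GLCMConfig = GLCMConfig()) -> TextureFeatures:
    """quantize -> per-angle GLCM -> normalize -> features, averaged over angles."""
    if mask is not None and not np.asarray(mask, dtype=bool).any():
        raise ValueError("extract_features: empty ROI mask")
    grid = quantize(image, config.levels, mask)
    per_angle = []
    for angle in config.angles:
        glcm = compute_glcm(grid, config, angle)
        if glcm.degenerate:
            raise ValueError(
                f"extract_features: no valid pixel pair at angle {angle} "
                f"(ROI too small for distance {config.distance})")
        per_angle.append(glcm_features(glcm))
    n = len(per_angle)
    return TextureFeatures(
        contrast=sum(f.contrast for f in per_angle) / n,
        dissimilarity=sum(f.dissimilarity for f in per_angle) / n,
        homogeneity=sum(f.homogeneity for f in per_angle) / n,
        energy=sum(f.energy for f in per_angle) / n,
        correlation=sum(f.correlation for f in per_angle) / n,
        entropy=sum(f.entropy for f in per_angle) / n,
        correlation_degenerate=any(f.correlation_degenerate for f in per_angle),
    )


def features_to_row(feats: TextureFeatures) -> list[float]:
    """Feature values in the canonical CSV column order."""
    return [getattr(feats, c) for c in FEATURE_COLUMNS]
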