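"""Seeded affine data augmentation: rotation, shift, shear, zoom, flips.

One random draw per enabled transform, composed into a *single* affine
map about the image center (rotation ∘ shear ∘ zoom ∘ shift) and applied
with one bilinear resampling pass — sequential resamplings would
compound interpolation blur.  Vacated pixels are filled per
``fill_mode``; values stay inside [0, 1] for every mode (constant fill
uses 0).  Optional intensity jitter (multiplicative gain plus additive
offset) is off by default.

Augmented copies inherit the class label but carry no ground-truth mask:
in the training pipeline augmentation happens after segmentation and
feature extraction, so masks of copies are never consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import Image, UNIT
from .phantom import LabeledImage

__all__ = ["AugmentConfig", "affine_params_matrix", "apply_affine",
           "random_transform", "augment_dataset"]

_FILL_MODES = {"nearest": "nearest", "reflect": "reflect", "constant": "constant"}


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random transforms; each draw is uniform over its range."""

    rotation_range: float = 20.0        # degrees, drawn from [-r, +r]
    width_shift: float = 0.1            # fraction of width, [-s, +s]
    height_shift: float = 0.1           # fraction of height, [-s, +s]
    shear_range: float = 10.0           # degrees, [-s, +s]
    zoom_range: tuple[float, float] = (0.9, 1.1)
    horizontal_flip: bool = True        # applied with probability 1/2
    vertical_flip: bool = True
    fill_mode: str = "nearest"
    constant_value: float = 0.0
    intensity_jitter: bool = False      # gain in [0.9,1.1], offset in [-0.05,0.05]
    copies_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fill_mode not in _FILL_MODES:
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}; "
                             f"choose from {sorted(_FILL_MODES)}")
        lo, hi = self.zoom_range
        if not (0 < lo <= hi):
            raise ValueError("zoom interval must be positive and ordered")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


def affine_params_matrix(rotation_deg: float, shear_deg: float,
                         zoom: float, shift_rc: tuple[float, float],
                         shape: tuple[int, int]) -> np.ndarray:
    """Homogeneous 3x3 matrix for rotation ∘ shear ∘ zoom ∘ shift about center.

    Coordinates are (row, col); shifts are in pixels.
    """
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    th = math.radians(rotation_deg)
    sh = math.radians(shear_deg)

    rot = np.array([[math.cos(th), -math.sin(th), 0],
                    [math.sin(th), math.cos(th), 0],
                    [0, 0, 1]])
    shear = np.array([[1, math.tan(sh), 0],
                      [0, 1, 0],
                      [0, 0, 1]])
    zoom_m = np.diag([zoom, zoom, 1.0])
    shift = np.array([[1, 0, shift_rc[0]],
                      [0, 1, shift_rc[1]],
                      [0, 0, 1]])
    to_center = np.array([[1, 0, cy], [0, 1, cx], [0, 0, 1]])
    from_center = np.array([[1, 0, -cy], [0, 1, -cx], [0, 0, 1]])
    return to_center @ rot @ shear @ zoom_m @ shift @ from_center


def apply_affine(image: Image, matrix: np.ndarray, fill_mode: str = "nearest",
                 constant_value: float = 0.0) -> Image:
    """Resample through the inverse of ``matrix`` with bilinear interpolation."""
    inv = np.linalg.inv(matrix)
    out = ndimage.affine_transform(
        image.pixels, inv[:2, :2], offset=inv[:2, 2], order=1,
        mode=_FILL_MODES[fill_mode], cval=constant_value)
    hi = 1.0 if image.value_range == UNIT else 255.0
    return Image(np.clip(out, 0.0, hi), image.value_range)


def random_transform(image: Image, config: AugmentConfig,
                     draw_seed: int) -> Image:
    """Apply one randomly drawn composed transform; deterministic per seed."""
    if image.value_range != UNIT:
        raise ValueError("random_transform expects a unit-range image")
    rng = np.random.default_rng(draw_seed)
    rot = rng.uniform(-config.rotation_range, config.rotation_range)
    shear = rng.uniform(-config.shear_range, config.shear_range)
    zoom = rng.uniform(*config.zoom_range)
    dy = rng.uniform(-config.height_shift, config.height_shift) * image.height
    dx = rng.uniform(-config.width_shift, config.width_shift) * image.width
    flip_h = config.horizontal_flip and rng.random() < 0.5
    flip_v = config.vertical_flip and rng.random() < 0.5
    gain, offset = 1.0, 0.0
    if config.intensity_jitter:
        gain = rng.uniform(0.9, 1.1)
        offset = rng.uniform(-0.05, 0.05)

    mat = affine_params_matrix(rot, shear, zoom, (dy, dx), image.pixels.shape)
    out = apply_affine(image, mat, config.fill_mode, config.constant_value)
    px = out.pixels
    if flip_h:
        px = px[:, ::-1]
    if flip_v:
        px = px[::-1, :]
    if config.intensity_jitter:
        px = np.clip(px * gain + offset, 0.0, 1.0)
    return Image(np.ascontiguousarray(px), UNIT)


def augment_dataset(dataset: list[LabeledImage],
                    config: AugmentConfig = AugmentConfig()) -> list[LabeledImage]:
    """Originals plus ``copies_per_image`` transformed copies of each.

    Output size is n * (1 + copies_per_image); copies inherit labels and
    carry no mask.  Per-copy seeds derive from ``config.seed`` so the
    same (dataset, config) always yields the same augmented set.
    """
    if not dataset:
        raise ValueError("augment_dataset: empty dataset")
    out = list(dataset)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(dataset) * max(config.copies_per_image, 1))
    s = 0
    for item in dataset:
        for _ in range(config.copies_per_image):
            img = random_transform(item.image, config, int(seeds[s] % (2**31)))
            out.append(LabeledImage(img, item.label, None))
            s += 1
    return out
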