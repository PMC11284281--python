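"""Seeded synthetic brain-MR-like phantoms with ground-truth tumor masks.

Each phantom is an elliptical "brain" of moderate intensity on a dark
background.  Tumor-class phantoms additionally contain one compact
hyperintense elliptical blob with higher-variance internal texture,
mirroring how lesions present on the scans this pipeline targets: bright,
compact, and texturally distinct.  Tumor hyperintensity is a deliberate
construction choice — the segmentation stage identifies the tumor as the
brightest cluster, so ground-truth masks stay meaningful end to end.

Texture is realized as seeded Gaussian noise smoothed with a Gaussian
filter (a low-frequency random field); pixel noise is i.i.d. Gaussian.
Everything is driven by ``numpy.random.default_rng`` so identical
(config, label, seed) triples produce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .image_io import Image, UNIT

__all__ = ["PhantomConfig", "LabeledImage", "generate_phantom", "generate_dataset",
           "TUMOR", "NON_TUMOR"]

TUMOR = "tumor"
NON_TUMOR = "non_tumor"

#: smoothing length (pixels) of the low-frequency texture fields
_TEXTURE_SMOOTHING = 4.0
#: retries when a sampled tumor does not fit inside the brain ellipse
_MAX_PLACEMENT_TRIES = 50


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity statistics of the generated phantoms.

    All intensities are on the unit scale; lengths are fractions of the
    image side so phantoms scale cleanly with ``size``.
    """

    size: int = 224
    brain_axes: tuple[float, float] = (0.42, 0.36)
    background_level: float = 0.35
    tumor_radius_range: tuple[float, float] = (0.06, 0.14)
    tumor_level: float = 0.85
    tumor_texture_sigma: float = 0.10
    background_texture_sigma: float = 0.03
    noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("size too small for a phantom")
        if not (0.0 <= self.background_level < self.tumor_level <= 1.0):
            raise ValueError("need 0 <= background_level < tumor_level <= 1 "
                             "(tumors are hyperintense)")
        lo, hi = self.tumor_radius_range
        if not (0.0 < lo <= hi):
            raise ValueError("tumor radii must be positive and ordered")
        for s in (self.tumor_texture_sigma, self.background_texture_sigma,
                  self.noise_sigma):
            if s < 0:
                raise ValueError("sigmas must be >= 0")


@dataclass(frozen=True)
class LabeledImage:
    """A phantom (unit-range image), its class label, and its ground truth.

    ``mask`` is the binary tumor footprint; it is all zeros for the
    non-tumor class and ``None`` for derived copies that intentionally
    carry no ground truth (see the augmentation stage).
    """

    image: Image
    label: Literal["tumor", "non_tumor"]
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.label not in (TUMOR, NON_TUMOR):
            raise ValueError(f"unknown label {self.label!r}")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != self.image.pixels.shape:
                raise ValueError("mask shape must match image shape")
            if self.label == NON_TUMOR and m.any():
                raise ValueError("non_tumor phantoms must have empty masks")
            if self.label == TUMOR and not m.any():
                raise ValueError("tumor phantoms must have nonempty masks")
            object.__setattr__(self, "mask", m)


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean low-frequency random field with pointwise SD ~ sigma."""
    if sigma == 0:
        return np.zeros((size, size))
    raw = rng.standard_normal((size, size))
    sm = ndimage.gaussian_filter(raw, _TEXTURE_SMOOTHING, mode="reflect")
    sd = sm.std()
    if sd == 0:  # degenerate only for size 1
        return np.zeros((size, size))
    return sm * (sigma / sd)


def _ellipse_mask(size: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    cy, cx = center
    ay, ax = axes
    return ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig = PhantomConfig(),
                     label: str = TUMOR, seed: int = 0) -> LabeledImage:
    """Generate one phantom; deterministic in (config, label, seed)."""
    if label not in (TUMOR, NON_TUMOR):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    n = config.size
    brain_ax = (config.brain_axes[0] * n, config.brain_axes[1] * n)
    center = ((n - 1) / 2.0, (n - 1) / 2.0)
    brain = _ellipse_mask(n, center, brain_ax)

    img = np.zeros((n, n))
    img[brain] = config.background_level
    img[brain] += _smooth_field(rng, n, config.background_texture_sigma)[brain]

    mask = np.zeros((n, n), dtype=bool)
    if label == TUMOR:
        r_lo, r_hi = (f * n for f in config.tumor_radius_range)
        for _ in range(_MAX_PLACEMENT_TRIES):
            ry = rng.uniform(r_lo, r_hi)
            rx = rng.uniform(r_lo, r_hi)
            # uniform position inside the brain ellipse via rejection
            ty = center[0] + rng.uniform(-brain_ax[0], brain_ax[0])
            tx = center[1] + rng.uniform(-brain_ax[1], brain_ax[1])
            # the whole tumor ellipse must sit inside the brain ellipse:
            # conservative check on the enclosing circle radius
            margin = max(ry, rx)
            d = (((ty - center[0]) / (brain_ax[0] - margin)) ** 2
                 + ((tx - center[1]) / (brain_ax[1] - margin)) ** 2
                 if brain_ax[0] > margin and brain_ax[1] > margin else 2.0)
            if d <= 1.0:
                break
        else:
            raise RuntimeError("could not place a tumor inside the brain ellipse; "
                               "tumor_radius_range is too large for brain_axes")
        mask = _ellipse_mask(n, (ty, tx), (ry, rx))
        img[mask] = config.tumor_level
        img[mask] += _smooth_field(rng, n, config.tumor_texture_sigma)[mask]

    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, (n, n))
    img = np.clip(img, 0.0, 1.0)
    return LabeledImage(Image(img, UNIT), label, mask)


def generate_dataset(n_per_class: int, config: PhantomConfig = PhantomConfig(),
                     seed: int = 0) -> list[LabeledImage]:
    """Balanced dataset of ``n_per_class`` tumor and non-tumor phantoms.

    Per-item seeds are derived deterministically from the master seed via
    ``numpy.random.SeedSequence.spawn``, so the collection is reproducible
    and items are independent.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    children = np.random.SeedSequence(seed).generate_state(2 * n_per_class)
    out: list[LabeledImage] = []
    for i in range(n_per_class):
        out.append(generate_phantom(config, TUMOR, int(children[2 * i] % (2**31))))
        out.append(generate_phantom(config, NON_TUMOR,
                                    int(children[2 * i + 1] % (2**31))))
    return out
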