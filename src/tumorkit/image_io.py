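"""Image container and the preprocessing chain resize -> normalize -> Gaussian blur.

All downstream stages (segmentation, texture, the classifier) consume
2-D grayscale images.  Two value ranges are tracked explicitly so that
normalization can never be applied twice by accident:

``raw8``
    real values in [0, 255]; integers straight off an 8-bit file, or
    reals after bilinear resampling of such a file.
``unit``
    real values in [0, 1], the range every analysis stage expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage, UnidentifiedImageError
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "Image",
    "PreprocessConfig",
    "load_image",
    "save_image",
    "resize",
    "normalize",
    "gaussian_blur",
    "preprocess",
]

RAW8 = "raw8"
UNIT = "unit"

#: kernel truncation radius for the Gaussian blur, in standard deviations
BLUR_TRUNCATE = 4.0


@dataclass(frozen=True)
class Image:
    """A 2-D grayscale image with an explicit value range.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Intensity values.  Stored as float64.
    value_range : {"raw8", "unit"}
        ``raw8`` pixels lie in [0, 255], ``unit`` pixels in [0, 1].
    """

    pixels: np.ndarray
    value_range: str = RAW8

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"image must be a 2-D grid, got shape {arr.shape}")
        if self.value_range not in (RAW8, UNIT):
            raise ValueError(f"unknown value_range {self.value_range!r}")
        hi = 255.0 if self.value_range == RAW8 else 1.0
        if arr.min() < -1e-9 or arr.max() > hi + 1e-9:
            raise ValueError(
                f"pixel values [{arr.min():g}, {arr.max():g}] outside the "
                f"declared {self.value_range} range [0, {hi:g}]"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the preprocessing chain.

    ``blur_sigma`` is in units of *resized* pixels because blurring runs
    after resizing.
    """

    target_height: int = 224
    target_width: int = 224
    blur_sigma: float = 1.0
    blur_enabled: bool = True

    def __post_init__(self) -> None:
        if self.target_height < 1 or self.target_width < 1:
            raise ValueError("target dimensions must be >= 1")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be > 0")


def load_image(path: str | Path) -> Image:
    """Read a PNG/JPEG file as a raw8 grayscale :class:`Image`.

    RGB inputs are converted to luminance (ITU-R 601 weights, Pillow's
    ``L`` mode).
    """
    path = Path(path)
    try:
        with PILImage.open(path) as im:
            gray = im.convert("L")
            arr = np.asarray(gray, dtype=np.float64)
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    return Image(arr, RAW8)


def save_image(image: Image, path: str | Path) -> None:
    """Write an image as lossless 8-bit PNG (unit images are scaled by 255)."""
    arr = image.pixels
    if image.value_range == UNIT:
        arr = arr * 255.0
    PILImage.fromarray(np.clip(np.rint(arr), 0, 255).astype(np.uint8)).save(
        Path(path), format="PNG"
    )


def resize(image: Image, config: PreprocessConfig = PreprocessConfig()) -> Image:
    """Bilinearly rescale to the target size; aspect ratio is not preserved."""
    if (image.height, image.width) == (config.target_height, config.target_width):
        return image
    out = _sk_resize(
        image.pixels,
        (config.target_height, config.target_width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return Image(out, image.value_range)


def normalize(image: Image) -> Image:
    """Scale raw8 intensities into [0, 1] by dividing by 255."""
    if image.value_range != RAW8:
        raise ValueError(
            "image is already normalized; normalizing twice would corrupt the scale"
        )
    return Image(image.pixels / 255.0, UNIT)


def gaussian_blur(image: Image, sigma: float) -> Image:
    """Convolve with a normalized 2-D Gaussian kernel (reflect boundary)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = ndimage.gaussian_filter(
        image.pixels, sigma=sigma, mode="reflect", truncate=BLUR_TRUNCATE
    )
    return Image(np.clip(out, 0.0, 255.0 if image.value_range == RAW8 else 1.0),
                 image.value_range)


def preprocess(image: Image, config: PreprocessConfig = PreprocessConfig()) -> Image:
    """resize -> normalize -> (optional) blur; returns a unit-range image."""
    if image.value_range != RAW8:
        raise ValueError("preprocess expects a raw8 image")
    out = normalize(resize(image, config))
    if config.blur_enabled:
        out = gaussian_blur(out, config.blur_sigma)
    return out
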