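"""Brightness-based preprocessing of palm scans.

Palm images are acquired on a flat-bed scanner as a bright hand on a darker
background.  Preprocessing converts the RGB scan to 8-bit grayscale and
suppresses the background with a mean-brightness threshold filter: every
pixel at least as bright as the image mean is kept unchanged, everything
else is zeroed.  The surviving pixels are the raw material for silhouette
segmentation downstream.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "FilteredImage",
    "rgb_to_gray",
    "mean_brightness",
    "brightness_filter",
    "read_image",
    "write_image",
]

# ITU-R BT.601 luminance weights, the de-facto rgb2gray convention.
_BT601 = np.array([0.2989, 0.5870, 0.1140])


class FilteredImage(NamedTuple):
    """A thresholded grayscale image plus the threshold that produced it.

    Every pixel is either 0 or equal to the corresponding grayscale pixel,
    and every nonzero pixel is >= ``threshold``.
    """

    pixels: np.ndarray  # M x N uint8
    threshold: float  # the mean brightness H used as cutoff


def _validate_gray(gray: np.ndarray) -> np.ndarray:
    gray = np.asarray(gray)
    if gray.ndim != 2 or gray.size == 0:
        raise InvalidInputError(
            f"expected a nonempty 2-D grayscale image, got shape {gray.shape}"
        )
    return gray


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Convert an M x N x 3 RGB image to 8-bit grayscale luminance.

    Uses the BT.601 weights 0.2989 R + 0.5870 G + 0.1140 B and rounds half
    up to the nearest integer.  A 2-D input is assumed to be grayscale
    already and is passed through unchanged.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("empty image")
    if image.ndim == 2:
        return image.astype(np.uint8, copy=False)
    if image.ndim != 3 or image.shape[2] < 3:
        raise InvalidInputError(
            f"expected an M x N x 3 RGB image, got shape {image.shape}"
        )
    lum = image[..., :3].astype(np.float64) @ _BT601
    return np.floor(lum + 0.5).clip(0, 255).astype(np.uint8)


def mean_brightness(gray: np.ndarray) -> float:
    """Mean intensity H of a grayscale image, kept as an unrounded real."""
    gray = _validate_gray(gray)
    return float(gray.mean(dtype=np.float64))


def brightness_filter(gray: np.ndarray) -> FilteredImage:
    """Zero every pixel strictly below the image's mean brightness.

    Pixels with ``g >= H`` survive unchanged (a constant image therefore
    passes unfiltered, since every pixel sits exactly on the threshold).
    """
    gray = _validate_gray(gray)
    h = mean_brightness(gray)
    out = np.where(gray.astype(np.float64) >= h, gray, 0).astype(gray.dtype)
    return FilteredImage(pixels=out, threshold=h)


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a uint8 array (RGB or grayscale)."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path, pixels: np.ndarray) -> None:
    """Write a uint8 image to PNG (or any format imageio infers)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))
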