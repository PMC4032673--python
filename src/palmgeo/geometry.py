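"""Silhouette geometry: segmentation, pose normalization, measurement.

The classifier consumes three geometric invariants of the hand silhouette:
its length along the major axis, the maximal palm breadth perpendicular to
it, and their ratio.  Because subjects place the hand freely on the scanner
(no pegs), the silhouette arrives rotated and shifted; measurement is
therefore preceded by a pose normalization that centers the silhouette and
rotates its principal axis (from the second central image moments) to
vertical, fingers up.

Feature extraction is the composition

    rgb_to_gray -> brightness_filter -> segment_hand -> normalize_pose
        -> measure_features

exposed as :func:`extract`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform

from .errors import (
    InvalidInputError,
    MeasurementError,
    OrientationUndefinedError,
    PalmGeoError,
    SegmentationError,
)
from .preprocess import FilteredImage, brightness_filter, rgb_to_gray

__all__ = [
    "GeometryFeatures",
    "segment_hand",
    "normalize_pose",
    "measure_features",
    "extract",
    "DEFAULT_MIN_AREA",
]

#: Minimum connected-component area (px) accepted as a hand silhouette.
DEFAULT_MIN_AREA = 500

#: Relative anisotropy below which the principal axis is deemed undefined.
_ISOTROPY_TOL = 1e-9


@dataclass(frozen=True)
class GeometryFeatures:
    """Geometric feature vector of one hand silhouette (pixel units)."""

    length_px: float  # extent along the major (vertical, normalized) axis
    width_px: float  # maximal breadth of the proximal half (the palm)
    aspect_ratio: float  # length / width, dimensionless

    def as_array(self) -> np.ndarray:
        return np.array([self.length_px, self.width_px, self.aspect_ratio])


def _as_pixels(filtered) -> np.ndarray:
    if isinstance(filtered, FilteredImage):
        return filtered.pixels
    return np.asarray(filtered)


def segment_hand(filtered, min_area: int = DEFAULT_MIN_AREA) -> np.ndarray:
    """Extract the hand silhouette from a brightness-filtered image.

    Nonzero pixels are closed with a 3x3 structuring element, the largest
    8-connected component is kept (ties broken by the smaller top-left
    bounding-box coordinate), and interior holes are filled.  Returns a
    boolean mask with exactly one connected component.

    Raises :class:`SegmentationError` if the image is all zero or the
    surviving component is smaller than ``min_area`` pixels.
    """
    pixels = _as_pixels(filtered)
    full = pixels > 0
    if not full.any():
        raise SegmentationError("no nonzero pixels to segment")
    # work on the bounding box (plus margin for the closing) for speed
    rr, cc = np.nonzero(full)
    r0 = max(0, rr.min() - 2)
    c0 = max(0, cc.min() - 2)
    box = (slice(r0, min(full.shape[0], rr.max() + 3)),
           slice(c0, min(full.shape[1], cc.max() + 3)))
    mask = full[box]
    struct = np.ones((3, 3), dtype=bool)
    mask = ndimage.binary_closing(mask, structure=struct)
    labels, n = ndimage.label(mask, structure=struct)  # 8-connectivity
    if n == 0:
        raise SegmentationError("closing removed every pixel")
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) > 1:
        # deterministic tie-break: smallest (min_row, min_col) of the bbox
        slices = ndimage.find_objects(labels)
        key = [(slices[c - 1][0].start, slices[c - 1][1].start) for c in candidates]
        best = candidates[int(np.lexsort((
            [k[1] for k in key], [k[0] for k in key]))[0])]
    else:
        best = candidates[0]
    if best_area < min_area:
        raise SegmentationError(
            f"largest component has {int(best_area)} px < min_area={min_area}"
        )
    out = np.zeros_like(full)
    out[box] = ndimage.binary_fill_holes(labels == best)
    return out


def _central_moments(mask: np.ndarray) -> tuple[float, float, float, float, float]:
    rows, cols = np.nonzero(mask)
    r0 = rows.mean()
    c0 = cols.mean()
    dr = rows - r0
    dc = cols - c0
    return r0, c0, float((dr * dr).mean()), float((dc * dc).mean()), float((dr * dc).mean())


def principal_axis_angle_deg(mask: np.ndarray) -> float:
    """Angle (degrees) of the silhouette's principal axis away from vertical.

    Computed from the second central moments; positive angles follow the
    counter-clockwise convention of ``skimage.transform.rotate`` so that
    rotating the mask by the *negative* of this angle makes the axis
    vertical.  Raises :class:`OrientationUndefinedError` for isotropic
    silhouettes (e.g. a perfect disc).
    """
    _, _, mu_rr, mu_cc, mu_rc = _central_moments(mask)
    anisotropy = math.hypot(mu_rr - mu_cc, 2.0 * mu_rc)
    if anisotropy <= _ISOTROPY_TOL * (mu_rr + mu_cc):
        raise OrientationUndefinedError(
            "second central moments are isotropic; principal axis undefined"
        )
    # Angle of the major axis measured from the row (vertical) axis.
    theta = 0.5 * math.atan2(2.0 * mu_rc, mu_rr - mu_cc)
    return math.degrees(theta)


def normalize_pose(mask: np.ndarray) -> np.ndarray:
    """Rotate and center a silhouette so pose drops out of measurement.

    The mask is rotated so the principal axis of its second central moments
    is vertical, flipped if needed so the heavier half (the palm) is at the
    bottom, cropped to its bounding box, and padded so the centroid sits at
    the raster center.  Output raster size adapts to the rotated mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    rr, cc = np.nonzero(mask)
    mask = mask[rr.min(): rr.max() + 1, cc.min(): cc.max() + 1]
    angle = principal_axis_angle_deg(mask)
    if abs(angle) > 1e-12:
        rot = transform.rotate(
            mask.astype(np.float64), -angle, resize=True, order=1
        ) > 0.5
    else:
        rot = mask.copy()
    if not rot.any():
        raise InvalidInputError("mask vanished during rotation")

    # Fingers-up disambiguation: the palm half carries more mass, so if the
    # rows above the centroid outweigh the rows below, flip vertically.
    rows = np.nonzero(rot)[0]
    r0 = rows.mean()
    if np.count_nonzero(rows < r0) > np.count_nonzero(rows > r0):
        rot = rot[::-1]

    # Crop to bounding box, then pad so the centroid is the raster center.
    rr, cc = np.nonzero(rot)
    rot = rot[rr.min(): rr.max() + 1, cc.min(): cc.max() + 1]
    rr, cc = np.nonzero(rot)
    h, w = rot.shape
    rc = int(round(rr.mean()))
    cc_ = int(round(cc.mean()))
    half_r = max(rc, h - 1 - rc)
    half_c = max(cc_, w - 1 - cc_)
    out = np.zeros((2 * half_r + 1, 2 * half_c + 1), dtype=bool)
    out[half_r - rc: half_r - rc + h, half_c - cc_: half_c - cc_ + w] = rot
    return out


def measure_features(mask: np.ndarray) -> GeometryFeatures:
    """Measure length, palm width, and aspect ratio of a normalized mask.

    Length is the number of rows the silhouette spans.  Width is the
    maximal count of silhouette pixels over the rows of the proximal
    (bottom) half of that span — the palm is the widest solid region there,
    and the half restriction excludes the fingers without any landmark
    detection.  Aspect ratio is length / width.
    """
    mask = np.asarray(mask, dtype=bool)
    rows = np.nonzero(mask)[0]
    if rows.size == 0:
        raise InvalidInputError("empty mask")
    r_min, r_max = int(rows.min()), int(rows.max())
    length = r_max - r_min + 1
    mid = r_min + length // 2
    width = int(mask[mid: r_max + 1].sum(axis=1).max())
    if width == 0:
        raise MeasurementError("zero palm width in the proximal half")
    return GeometryFeatures(
        length_px=float(length),
        width_px=float(width),
        aspect_ratio=length / width,
    )


_STAGES = (
    ("rgb_to_gray", rgb_to_gray),
    ("brightness_filter", brightness_filter),
    ("segment_hand", segment_hand),
    ("normalize_pose", normalize_pose),
    ("measure_features", measure_features),
)


def extract(image: np.ndarray, min_area: int = DEFAULT_MIN_AREA) -> GeometryFeatures:
    """Run the full feature-extraction pipeline on one RGB palm image.

    Stage errors propagate with the failing stage's name attached as the
    exception's ``stage`` attribute.
    """
    value = image
    for name, stage in _STAGES:
        try:
            if stage is segment_hand:
                value = stage(value, min_area=min_area)
            else:
                value = stage(value)
        except PalmGeoError as err:
            err.stage = name
            raise
    return value
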