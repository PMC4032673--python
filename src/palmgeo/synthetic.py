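"""Synthetic palm-scan generator.

The reference database this package targets — 30 subjects, 6 scans each
(3 left + 3 right), 15 male, bright hand on a darker background, scanned
at fixed resolution — is private.  This module emulates its statistical
structure so every pipeline stage is testable without any download:

* :func:`render_hand` draws a single hand silhouette (rectangular palm,
  five capsule fingers on the distal edge) with known ground-truth
  dimensions, pose (rotation/shift), and pixel noise;
* :func:`sample_population` draws a whole database with sex-dimorphic size
  distributions and within-subject jitter;
* :func:`sample_feature_table` skips rendering and draws (length, width,
  ratio) feature rows directly from the same per-sex distributions, for
  fast classifier tests.

All generators are pure functions of (spec, seed).  Sizes follow
per-sex lognormal distributions (guaranteeing positivity): by default male
palm length and width means are 1.1x the female means with a common 4%
coefficient of variation — an engineering stand-in for sexual dimorphism,
since the reference database reports no measurement distributions.
The default canvas is 632 x 450, the reference scans' 2528 x 1800 at
quarter scale, keeping tests fast; pass ``canvas_size`` for other scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw

from .errors import InvalidInputError, RenderingError
from .pssvm import LabeledDataset

__all__ = [
    "HandParams",
    "PopulationSpec",
    "render_hand",
    "sample_population",
    "sample_feature_table",
    "DEFAULT_CANVAS",
]

DEFAULT_CANVAS = (632, 450)  # rows x cols; quarter-scale flatbed scan

#: Relative finger lengths (thumb .. little), as fractions of palm length.
_FINGER_LENGTH_FRACS = (0.55, 0.80, 0.90, 0.85, 0.65)

#: Finger width as a fraction of palm width (5 fingers fit in 5 slots).
_FINGER_WIDTH_FRAC = 0.16

_MIN_CONTRAST = 40  # segmentable hand/background intensity gap


@dataclass(frozen=True)
class HandParams:
    """Ground-truth geometry and photometry of one synthetic hand."""

    palm_length_px: float = 200.0
    palm_width_px: float = 150.0
    finger_lengths_px: tuple[float, ...] = tuple(
        f * 200.0 for f in _FINGER_LENGTH_FRACS
    )
    finger_width_px: float = 150.0 * _FINGER_WIDTH_FRAC
    rotation_deg: float = 0.0
    shift_px: tuple[int, int] = (0, 0)  # (rows down, cols right)
    hand_intensity: int = 200
    background_intensity: int = 40
    noise_sd: float = 8.0

    def __post_init__(self) -> None:
        extents = (self.palm_length_px, self.palm_width_px,
                   self.finger_width_px, *self.finger_lengths_px)
        if any(e <= 0 for e in extents):
            raise InvalidInputError("all hand extents must be positive")
        if len(self.finger_lengths_px) != 5:
            raise InvalidInputError("exactly five finger lengths required")
        if not -30.0 <= self.rotation_deg <= 30.0:
            raise InvalidInputError("rotation_deg must lie in [-30, 30]")
        if self.hand_intensity - self.background_intensity < _MIN_CONTRAST:
            raise InvalidInputError(
                f"hand/background contrast must be >= {_MIN_CONTRAST}"
            )
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")

    # --- raster semantics: extents are drawn at integer-rounded sizes ----

    @property
    def drawn_palm(self) -> tuple[int, int]:
        return round(self.palm_length_px), round(self.palm_width_px)

    @property
    def drawn_fingers(self) -> tuple[tuple[int, int], ...]:
        w = round(self.finger_width_px)
        return tuple((round(l), w) for l in self.finger_lengths_px)

    @property
    def total_length_px(self) -> float:
        """Ground-truth hand length: palm plus longest finger plus its cap."""
        pl, _ = self.drawn_palm
        return pl + max(l + w / 2.0 for l, w in self.drawn_fingers)

    @property
    def analytic_area_px(self) -> float:
        """Area of the composed silhouette (rectangles + semicircular caps)."""
        pl, pw = self.drawn_palm
        area = float(pl * pw)
        for l, w in self.drawn_fingers:
            area += l * w + math.pi * (w / 2.0) ** 2 / 2.0
        return area


def _silhouette(params: HandParams, canvas_size: tuple[int, int]) -> np.ndarray:
    """Draw the upright silhouette centered on the canvas (no pose/noise)."""
    nrows, ncols = canvas_size
    pl, pw = params.drawn_palm
    fingers = params.drawn_fingers
    total = pl + max(l + (w + 1) // 2 for l, w in fingers)
    if total >= nrows or pw >= ncols:
        raise RenderingError(
            f"hand ({total} x {pw}) does not fit canvas {canvas_size}"
        )
    mask = np.zeros(canvas_size, dtype=bool)
    top = (nrows - total) // 2 + (total - pl)  # palm's top row
    c0 = ncols // 2 - pw // 2
    mask[top: top + pl, c0: c0 + pw] = True
    # five equal slots across the palm's distal edge, one capsule each
    for i, (fl, fw) in enumerate(fingers):
        center = c0 + int(round((i + 0.5) * pw / 5.0))
        cl = center - fw // 2
        mask[top - fl: top, cl: cl + fw] = True
        rr, cc = draw.disk((top - fl, cl + (fw - 1) / 2.0), fw / 2.0,
                           shape=canvas_size)
        mask[rr, cc] = True
    return mask


def _posed_silhouette(params: HandParams, canvas_size: tuple[int, int]) -> np.ndarray:
    from skimage import transform

    mask = _silhouette(params, canvas_size)
    if params.rotation_deg != 0.0:
        mask = transform.rotate(
            mask.astype(np.float64), params.rotation_deg, resize=False, order=1
        ) > 0.5
    dr, dc = params.shift_px
    if dr or dc:
        shifted = np.zeros_like(mask)
        src_r = slice(max(0, -dr), mask.shape[0] - max(0, dr))
        src_c = slice(max(0, -dc), mask.shape[1] - max(0, dc))
        dst_r = slice(max(0, dr), mask.shape[0] - max(0, -dr))
        dst_c = slice(max(0, dc), mask.shape[1] - max(0, -dc))
        if (np.count_nonzero(mask) !=
                np.count_nonzero(mask[src_r, src_c])):
            raise RenderingError("shift pushes the hand out of the canvas")
        shifted[dst_r, dst_c] = mask[src_r, src_c]
        mask = shifted
    edge = (mask[0].any() or mask[-1].any() or
            mask[:, 0].any() or mask[:, -1].any())
    if edge:
        raise RenderingError("posed hand touches the canvas border (clipped)")
    return mask


def render_hand(
    params: HandParams,
    canvas_size: tuple[int, int] = DEFAULT_CANVAS,
    seed: int = 0,
) -> tuple[np.ndarray, HandParams]:
    """Render one RGB palm scan; returns (image, ground-truth params).

    Deterministic given ``seed`` (which drives only the Gaussian pixel
    noise).  Raises :class:`RenderingError` when the posed hand does not
    fit the canvas.
    """
    mask = _posed_silhouette(params, canvas_size)
    img = np.full(canvas_size, float(params.background_intensity))
    img[mask] = float(params.hand_intensity)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    gray = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return np.repeat(gray[:, :, None], 3, axis=2), params


@dataclass(frozen=True)
class PopulationSpec:
    """Statistical shape of a synthetic palm database.

    Defaults mirror the reference database layout (30 subjects x 6 images,
    15 male) with the default dimorphism: male size means 1.1x female,
    common CV 4%, within-subject jitter 1% of the subject mean.  Setting
    the male means equal to the female means yields a zero-dimorphism
    null population.
    """

    n_subjects: int = 30
    images_per_subject: int = 6
    n_male: int = 15
    female_palm_length_mean: float = 200.0
    female_palm_width_mean: float = 150.0
    male_palm_length_mean: float = 220.0
    male_palm_width_mean: float = 165.0
    cv: float = 0.04  # between-subject coefficient of variation
    within_subject_jitter_cv: float = 0.01
    rotation_range_deg: float = 15.0
    shift_range_px: int = 20
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_male <= self.n_subjects):
            raise InvalidInputError("need 0 <= n_male <= n_subjects")
        if self.n_subjects < 1 or self.images_per_subject < 1:
            raise InvalidInputError("need at least one subject and one image each")
        if self.cv < 0 or self.within_subject_jitter_cv < 0:
            raise InvalidInputError("coefficients of variation must be >= 0")

    def size_means(self, male: bool) -> tuple[float, float]:
        if male:
            return self.male_palm_length_mean, self.male_palm_width_mean
        return self.female_palm_length_mean, self.female_palm_width_mean


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Lognormal draw parameterized by its mean and coefficient of variation."""
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def _subject_draws(spec: PopulationSpec, rng: np.random.Generator):
    """Yield (subject_id, label, image_index, hand, length, width) rows."""
    half = spec.images_per_subject // 2
    for s in range(spec.n_subjects):
        male = s < spec.n_male
        len_mean, wid_mean = spec.size_means(male)
        base_len = _lognormal(rng, len_mean, spec.cv)
        base_wid = _lognormal(rng, wid_mean, spec.cv)
        for j in range(spec.images_per_subject):
            length = _lognormal(rng, base_len, spec.within_subject_jitter_cv)
            width = _lognormal(rng, base_wid, spec.within_subject_jitter_cv)
            hand = "L" if j < half else "R"
            yield s, (1 if male else -1), j, hand, float(length), float(width)


@dataclass(frozen=True)
class PopulationImage:
    """One rendered database entry with its ground truth."""

    image: np.ndarray
    subject_id: int
    hand: str  # "L" or "R"
    label: int  # +1 male, -1 female
    params: HandParams
    image_id: str = ""


def sample_population(
    spec: PopulationSpec,
    canvas_size: tuple[int, int] = DEFAULT_CANVAS,
) -> list[PopulationImage]:
    """Render a full synthetic database according to ``spec``.

    Subject base dimensions are drawn from the sex-specific lognormal;
    each image adds within-subject size jitter, a uniform rotation in
    ``[-rotation_range_deg, +rotation_range_deg]``, and a uniform integer
    shift.  Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    out: list[PopulationImage] = []
    for s, label, j, hand, length, width in _subject_draws(spec, rng):
        params = HandParams(
            palm_length_px=length,
            palm_width_px=width,
            finger_lengths_px=tuple(f * length for f in _FINGER_LENGTH_FRACS),
            finger_width_px=width * _FINGER_WIDTH_FRAC,
            rotation_deg=float(rng.uniform(-spec.rotation_range_deg,
                                           spec.rotation_range_deg)),
            shift_px=(int(rng.integers(-spec.shift_range_px, spec.shift_range_px + 1)),
                      int(rng.integers(-spec.shift_range_px, spec.shift_range_px + 1))),
            noise_sd=spec.noise_sd,
        )
        img, truth = render_hand(params, canvas_size,
                                 seed=int(rng.integers(2**31)))
        out.append(PopulationImage(
            image=img, subject_id=s, hand=hand, label=label, params=truth,
            image_id=f"s{s:02d}_{hand}{j % max(1, spec.images_per_subject // 2)}",
        ))
    return out


def sample_feature_table(
    spec: PopulationSpec, seed: int | None = None
) -> LabeledDataset:
    """Draw a (length, width, ratio) feature table without rendering.

    Uses the same two-level (subject base + within-subject jitter)
    lognormal scheme as :func:`sample_population`; the aspect ratio is
    computed as length / width.  ``seed`` overrides ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows, labels, groups = [], [], []
    for s, label, _, _, length, width in _subject_draws(spec, rng):
        rows.append([length, width, length / width])
        labels.append(label)
        groups.append(s)
    return LabeledDataset(
        X=np.asarray(rows),
        y=np.asarray(labels),
        feature_names=("length_px", "width_px", "aspect_ratio"),
        groups=np.asarray(groups),
    )
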