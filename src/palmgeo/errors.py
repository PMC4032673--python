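"""Exception hierarchy shared across the pipeline stages."""


class PalmGeoError(Exception):
    """Base class for all palmgeo errors.

    ``stage`` is attached by :func:`palmgeo.geometry.extract` when an error
    propagates out of a named pipeline stage.
    """

    stage: str | None = None


class InvalidInputError(PalmGeoError, ValueError):
    """An input violates a documented precondition (empty image, bad shape, ...)."""


class InvalidHyperparameterError(PalmGeoError, ValueError):
    """A hyperparameter is outside its admissible range (e.g. k <= 0)."""


class SegmentationError(PalmGeoError):
    """No usable hand silhouette could be segmented from the image."""


class OrientationUndefinedError(PalmGeoError):
    """The silhouette's second moments are isotropic; no principal axis exists."""


class MeasurementError(PalmGeoError):
    """Geometric measurement failed (e.g. zero palm width)."""


class RenderingError(PalmGeoError):
    """A synthetic hand does not fit its canvas."""


class SplitError(PalmGeoError):
    """A train/test split produced an unusable (empty or single-class) training set."""


class FormatError(PalmGeoError):
    """A feature table or config file violates the documented format."""
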