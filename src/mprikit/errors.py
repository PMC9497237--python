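"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`MprikitError`
so callers (and the pipeline driver) can catch one base class and report
the stage that failed.
"""


class MprikitError(Exception):
    """Base class for all mprikit errors."""


class ParameterError(MprikitError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(MprikitError):
    """Invalid or degenerate contour geometry."""


class LandmarkError(GeometryError):
    """A required anatomical landmark (RV insertion) is missing."""


class ExtractionError(MprikitError):
    """A region needed for signal extraction is empty or inconsistent."""


class NoBolusError(MprikitError):
    """A time-signal curve never rises above its baseline (no contrast arrival)."""


class WindowError(MprikitError):
    """Too few admissible frames to fit an upslope window."""


class DegenerateDataError(MprikitError):
    """Data admit no meaningful statistic (zero blood-pool upslope, all-tied samples, ...)."""


class FormatError(MprikitError):
    """An input file does not match the expected on-disk format."""
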