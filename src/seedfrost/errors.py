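"""Exception hierarchy for seedfrost.

Every error raised on bad user input derives from :class:`SeedfrostError`
so callers can catch the library's failures without swallowing bugs.
"""


class SeedfrostError(Exception):
    """Base class for all seedfrost errors."""


class FormatError(SeedfrostError):
    """A file is syntactically valid but missing required metadata."""


class CorruptFileError(SeedfrostError):
    """Header metadata and raw payload disagree (e.g. size mismatch)."""


class CalibrationError(SeedfrostError):
    """Reflectance calibration hit zero white-minus-dark denominators."""


class DegenerateInputError(SeedfrostError):
    """Input carries no usable signal (constant image, constant spectrum...)."""


class EmptyMaskError(SeedfrostError):
    """No connected component survived the minimum-area filter."""


class LayoutError(SeedfrostError):
    """A synthetic cube layout is geometrically invalid."""


class ConfigError(SeedfrostError):
    """A configuration value is inconsistent or out of range."""


class StratificationError(SeedfrostError):
    """A class is absent from a partition that must contain it."""
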