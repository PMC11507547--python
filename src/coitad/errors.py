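"""Typed exceptions raised by the coitad pipeline stages."""


class CoitadError(Exception):
    """Base class for all coitad errors."""


class FormatError(CoitadError):
    """Input text could not be parsed (ragged rows, malformed triplets)."""


class ShapeError(CoitadError):
    """Matrix has the wrong shape (non-square, or fewer than 2 bins)."""


class RangeError(CoitadError):
    """A bin index falls outside the declared matrix size."""


class ConfigurationError(CoitadError):
    """Parameters are inconsistent with the data (e.g. resolution too coarse)."""


class DegenerateInputError(CoitadError):
    """Input carries no usable signal (e.g. all feature columns constant)."""


class IntegrityError(CoitadError):
    """Segments are unordered, overlapping, or do not cover the diagonal."""
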