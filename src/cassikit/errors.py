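"""Exception hierarchy shared across the package.

All errors derive from :class:`CassiError` so callers can catch the package's
failures with a single ``except``; most also derive from the builtin they most
resemble (``ValueError`` for bad parameters, ``KeyError`` for bad config keys)
so untyped call sites behave conventionally.
"""


class CassiError(Exception):
    """Base class for all cassikit errors."""


class DimensionError(CassiError, ValueError):
    """Array shapes or grid dimensions are inconsistent."""


class RangeError(CassiError, ValueError):
    """A wavelength (or other coordinate) falls outside the calibrated range."""


class FormatError(CassiError, ValueError):
    """An on-disk artifact is malformed or inconsistent with its sidecar."""


class MetadataError(FormatError):
    """Required sidecar metadata is missing."""


class ConfigurationError(CassiError, ValueError):
    """A configuration value is unknown or inconsistent."""


class NumericError(CassiError, ArithmeticError):
    """An iterative computation produced non-finite values."""


class ResolutionError(CassiError, ValueError):
    """A requested pattern cannot be rendered at the configured pixel scale."""


class UndefinedContrastError(CassiError, ValueError):
    """Contrast of an all-zero intensity profile is undefined."""
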