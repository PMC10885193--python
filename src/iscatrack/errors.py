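"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (config errors -> 2,
input-format errors -> 3, empty-result errors -> 4).
"""


class IscatrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IscatrackError, ValueError):
    """A scalar parameter violates its documented domain."""


class ConfigurationError(IscatrackError, ValueError):
    """A configuration object is internally inconsistent."""


class InputFormatError(IscatrackError, ValueError):
    """An input file cannot be parsed as the expected format."""


class InvalidWindowError(InvalidParameterError):
    """Background window does not fit the movie length."""


class DegenerateBackgroundError(IscatrackError, ValueError):
    """Background estimate is zero everywhere; contrast is undefined."""


class DegenerateRegionError(IscatrackError, ValueError):
    """A segmented region has zero total weight."""


class EmptySampleError(IscatrackError, ValueError):
    """A statistic was requested on an empty sample."""


class DegenerateFitError(IscatrackError, ValueError):
    """A distribution fit is undefined for this sample (zero spread)."""
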