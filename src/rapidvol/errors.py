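"""Exception types raised across the pipeline."""


class RapidvolError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RapidvolError, ValueError):
    """Invalid generator or run configuration."""


class ParameterError(RapidvolError, ValueError):
    """Invalid argument to an analysis operation."""


class DataError(RapidvolError, ValueError):
    """Input data violate a precondition (non-finite, empty, wrong shape)."""


class AlignmentError(DataError):
    """Two inputs that must share participants or grids do not."""


class DegenerateDataError(DataError):
    """A statistic is undefined on the given data (e.g. constant input)."""


class SchemaError(DataError):
    """An external file does not follow the documented layout."""
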