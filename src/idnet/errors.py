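"""Exception hierarchy.

All idnet-raised errors derive from :class:`IdnetError` so callers can catch
pipeline failures without masking programming errors.
"""


class IdnetError(Exception):
    """Base class for all idnet errors."""


class ConfigurationError(IdnetError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(IdnetError):
    """A file could not be read in the requested/declared format."""


class ParameterError(IdnetError):
    """An analysis parameter outside its valid range (band edges, density, ...)."""


class DataError(IdnetError):
    """Input data insufficient or inconsistent for the requested operation."""


class LabelError(IdnetError):
    """A channel or class label is unknown, duplicated, or missing."""


class AlignmentError(IdnetError):
    """Two objects that must share a grid (densities, metrics) do not."""
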