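"""Exception hierarchy shared across the package."""


class VasowaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VasowaveError, ValueError):
    """A configuration value violates its documented constraints."""


class SchemaError(VasowaveError, ValueError):
    """An input file does not match the expected schema (columns, channels)."""


class ParseError(VasowaveError, ValueError):
    """An input file is structurally readable but its content is invalid."""


class FormatError(VasowaveError, ValueError):
    """A record cannot be represented in the requested on-disk format."""


class InsufficientDataError(VasowaveError, ValueError):
    """Not enough valid data to perform the requested operation."""


class AlignmentError(VasowaveError, RuntimeError):
    """No positive cross-correlation found within the lag search window."""
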