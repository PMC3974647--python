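"""Exception hierarchy shared across the package."""


class CircalucError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CircalucError, ValueError):
    """A model or configuration parameter is non-finite or out of range."""


class InsufficientDataError(CircalucError, ValueError):
    """A trace or fit set is too short/small for the requested operation."""


class SchemaError(CircalucError, ValueError):
    """An input file does not conform to the documented schema."""


class FormatError(CircalucError, ValueError):
    """An input file is structurally malformed (e.g. non-monotone time)."""


class NoSignalError(CircalucError, ValueError):
    """The trace carries no usable oscillatory signal (flat input)."""


class ConfigError(CircalucError, ValueError):
    """A simulation or run configuration is internally inconsistent."""
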