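"""Exception hierarchy shared across the pipeline."""


class SmpullError(Exception):
    """Base class for all package errors."""


class ValidationError(SmpullError, ValueError):
    """A parameter or input violates a documented precondition."""


class UndefinedFractionError(ValidationError):
    """A proportion was requested over an empty collection."""


class FormatError(SmpullError, ValueError):
    """A file could not be parsed in the expected dialect."""


class ConfigError(SmpullError, ValueError):
    """A configuration file is missing required information."""


class BoundsError(SmpullError, IndexError):
    """A region of interest falls outside the image."""
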