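"""Exception hierarchy shared by all circscape modules."""


class CircscapeError(Exception):
    """Base class for all package errors."""


class FormatError(CircscapeError):
    """A file or string does not conform to its declared format."""


class ReferenceIntegrityError(CircscapeError):
    """An identifier could not be resolved against its reference table."""


class ConfigurationError(CircscapeError):
    """A required configuration value is missing or invalid."""


class AnalysisError(CircscapeError):
    """An analysis precondition is violated (degenerate input, too few samples...)."""
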