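"""Exception hierarchy shared across the pipeline."""


class SczSubtypesError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SczSubtypesError, ValueError):
    """An invalid configuration value; the message names the field."""


class ValidationError(SczSubtypesError, ValueError):
    """Input data violates a documented precondition."""


class DimensionError(ValidationError):
    """Matrices or tables that should be aligned are not."""


class ModelError(SczSubtypesError, RuntimeError):
    """A per-probe model could not be fitted (e.g. rank deficiency)."""


class ParseError(SczSubtypesError, ValueError):
    """A file could not be parsed; the message carries location detail."""
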