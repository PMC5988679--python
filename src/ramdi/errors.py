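"""Exception hierarchy shared across the package."""


class RamdiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RamdiError, ValueError):
    """A domain-object invariant was violated; the message names the invariant."""


class ParseError(RamdiError, ValueError):
    """A file could not be parsed; the message names the offending line/field."""


class DataError(RamdiError, ValueError):
    """Input samples are unusable for the requested operation."""


class ConfigurationError(RamdiError, ValueError):
    """A required configuration element (e.g. a phase annotation) is missing."""


class ComputationError(RamdiError, RuntimeError):
    """A pipeline stage could not produce a result; the message names the stage."""
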