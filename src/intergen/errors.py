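"""Exception hierarchy shared by all stages."""


class IntergenError(Exception):
    """Base class for all package errors."""


class FormatError(IntergenError):
    """A file does not conform to the expected dialect (bad cell, bad header)."""


class ValidationError(IntergenError):
    """An in-memory object violates a structural invariant."""


class ConfigurationError(IntergenError):
    """A configuration value is missing, unknown, or out of range."""


class NormalizationError(IntergenError):
    """Size-factor estimation is impossible on the given counts."""


class EstimationError(IntergenError):
    """A statistical estimate cannot be formed (e.g. too few replicates)."""
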