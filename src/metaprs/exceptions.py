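"""Exception hierarchy shared across the package."""


class MetaPRSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetaPRSError):
    """A configuration value is outside its documented range."""


class ScoreFileFormatError(MetaPRSError):
    """A scoring file violates the expected column schema."""


class ValidationError(MetaPRSError):
    """Data content fails validation (e.g. a non-ACGT allele)."""


class ContractError(MetaPRSError):
    """An operation was called on inputs violating its preconditions."""


class HarmonizationError(MetaPRSError):
    """Allele harmonization produced no usable variants."""
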