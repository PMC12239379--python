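"""Exception hierarchy shared across the package."""


class EpitrainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EpitrainError):
    """Invalid configuration value or unknown configuration key."""


class FormatError(EpitrainError):
    """Malformed on-disk artifact (duplicate ids, ragged rows, bad cells)."""


class DomainError(EpitrainError, ValueError):
    """Input outside the mathematical domain of an operation."""
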