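"""Exception hierarchy shared across the package."""


class DietFrailError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DietFrailError):
    """A config file / definition set is malformed or inconsistent."""


class ValidationError(DietFrailError):
    """Input data violates a contract (row-level problems are collected,
    not raised; this is for hard violations)."""


class DomainError(DietFrailError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
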