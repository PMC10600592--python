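"""Exception hierarchy shared across the package."""


class DraburdenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DraburdenError):
    """A configuration value violates an invariant or a file cannot be parsed."""


class DomainError(DraburdenError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(DraburdenError):
    """Observed and projected data cannot be compared (e.g. year mismatch)."""
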