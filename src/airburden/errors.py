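"""Exception hierarchy shared across the pipeline."""


class AirburdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AirburdenError):
    """A generator or run configuration is malformed."""


class SchemaError(AirburdenError):
    """An input table does not match its declared schema (missing/extra column, empty file)."""


class ValidationError(AirburdenError):
    """A value violates a domain-type invariant; message names the offending field."""


class DomainError(AirburdenError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UndefinedCorrelationError(DomainError):
    """Pearson correlation requested on a zero-variance series."""
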