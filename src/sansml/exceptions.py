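"""Exception types shared across the package."""


class SansmlError(Exception):
    """Base class for all package errors."""


class ValidationError(SansmlError, ValueError):
    """An input value violates a documented precondition (e.g. out-of-bounds parameter)."""


class DomainError(SansmlError, ValueError):
    """An argument lies outside the mathematical domain of the operation (e.g. q <= 0)."""


class ConfigurationError(SansmlError, ValueError):
    """An instrument/sampling configuration is inconsistent (e.g. empty sampling interval)."""


class UnsupportedOperationError(SansmlError, TypeError):
    """The operation does not apply to this model (e.g. 2-D kernel of an isotropic model)."""
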