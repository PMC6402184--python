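"""Exception taxonomy: configuration vs numeric-domain vs malformed-input."""


class CernetError(ValueError):
    """Base class for all package errors."""


class ConfigError(CernetError):
    """Invalid configuration (dimensions, thresholds, infeasible placement)."""


class DomainError(CernetError):
    """Arguments outside a function's mathematical domain."""


class InputError(CernetError):
    """Malformed or inconsistent input data."""
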