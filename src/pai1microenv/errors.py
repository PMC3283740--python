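"""Exception hierarchy shared across the package."""


class Pai1Error(Exception):
    """Base class for all package-specific errors."""


class DomainError(Pai1Error, ValueError):
    """An argument is outside the domain of an operation (e.g. out-of-bounds site)."""


class ConfigurationError(Pai1Error, ValueError):
    """A parameter or configuration value violates a documented contract."""


class ContractViolationError(Pai1Error, RuntimeError):
    """An operation was called on an agent in a state that forbids it."""


class SweepError(Pai1Error, RuntimeError):
    """A hysteresis sweep could not observe the required transition."""


class RunError(Pai1Error, RuntimeError):
    """A simulation run failed to reach its configured objective."""
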