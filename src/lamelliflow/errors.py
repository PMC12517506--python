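"""Exception types: configuration, domain, initialization, and integration errors."""


class LamelliflowError(Exception):
    """Base class for package errors."""


class ConfigError(LamelliflowError, ValueError):
    """Invalid or unknown configuration field."""


class DomainError(LamelliflowError, ValueError):
    """Input outside its mathematical or geometric domain."""


class InitializationError(LamelliflowError, RuntimeError):
    """Network self-assembly failed to produce a usable state."""


class InstabilityError(LamelliflowError, RuntimeError):
    """Euler integration produced a displacement larger than half a segment;
    the time step is too large for the configured stiffnesses."""


class ConvergenceError(LamelliflowError, RuntimeError):
    """Iterative relaxation failed to reach the requested residual."""
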