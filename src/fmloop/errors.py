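"""Exception hierarchy shared across the package."""


class FmloopError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FmloopError, ValueError):
    """An input lies outside the mathematical domain of an operation
    (e.g. a negative concentration or firing rate)."""


class ParameterError(FmloopError, ValueError):
    """A model parameter violates its admissible range."""


class FitError(FmloopError, RuntimeError):
    """A curve fit could not be carried out or did not converge."""


class ConvergenceError(FmloopError, RuntimeError):
    """A numerical procedure (integration, root finding, bisection)
    failed to reach its tolerance."""


class ConfigError(FmloopError, ValueError):
    """A configuration file is malformed or contains unknown keys."""
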