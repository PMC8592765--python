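"""Exception taxonomy shared across the package."""


class DermsegError(Exception):
    """Base class for all package errors."""


class ValidationError(DermsegError, ValueError):
    """Input violates a documented contract (shape, range, binarity...)."""


class ConfigError(DermsegError, ValueError):
    """A configuration value is out of range or an enum is unknown."""


class UndefinedMetricError(DermsegError, ZeroDivisionError):
    """The metric's denominator is empty (e.g. both masks empty)."""


class DegenerateInputError(DermsegError, ValueError):
    """Numerically degenerate input (e.g. a zero-mean colour channel)."""


class DivergenceError(DermsegError, RuntimeError):
    """Training produced a non-finite loss."""
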