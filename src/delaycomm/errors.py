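"""Exception types shared across the package."""


class DelaycommError(Exception):
    """Base class for package errors."""


class ConfigError(DelaycommError, ValueError):
    """Inconsistent or invalid network / signal configuration."""


class InvalidInputError(DelaycommError, ValueError):
    """Non-finite or structurally invalid numeric input."""


class InsufficientOscillationError(DelaycommError, RuntimeError):
    """A rate series does not contain enough peaks to define a rhythm."""


class InsufficientDataError(DelaycommError, RuntimeError):
    """Not enough samples / peaks for the requested statistic."""


class UnlockedPairError(DelaycommError, RuntimeError):
    """An operation that requires phase locking was called on an unlocked pair."""


class UndefinedCorrelationError(DelaycommError, ValueError):
    """Correlation requested between series where one has zero variance."""
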