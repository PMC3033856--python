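"""Exception hierarchy for the FHR screening pipeline."""


class FhrScreenError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FhrScreenError, ValueError):
    """Malformed or out-of-contract input data."""


class MonotonicSignalError(FhrScreenError):
    """The signal (or current residual) has fewer than two maxima or two
    minima, so no intrinsic mode function can be extracted from it."""


class EmptyRetentionError(FhrScreenError):
    """Denoising would discard every decomposition component."""


class ConfigError(FhrScreenError):
    """Invalid pipeline configuration."""
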