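"""Exception types shared across the package."""


class ThermoscreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(ThermoscreenError, ValueError):
    """An argument violates a documented precondition."""


class NoGrowthError(ThermoscreenError):
    """A culture shows no optical-density increase; doubling time is undefined."""


class InvalidAssayError(ThermoscreenError):
    """A qPCR standard series is unusable (non-negative slope, degenerate Cq)."""


class UndefinedFitError(ThermoscreenError):
    """A regression cannot be fit (zero predictor variance, too few points)."""
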