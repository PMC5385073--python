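"""Exception types shared across the package."""


class MetagutError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MetagutError, ValueError):
    """Raised when an input violates a documented precondition."""


class EmptySampleError(MetagutError, ValueError):
    """Raised when a computation requires a non-empty sample row."""


class UndefinedEffectError(MetagutError, ZeroDivisionError):
    """Raised when an effect size is undefined (reference mean is zero)."""


class MissingFeatureError(MetagutError, KeyError):
    """Raised when a required feature is absent from a result set."""
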