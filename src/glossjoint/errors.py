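"""Exception and warning types shared across the package."""


class GlossjointError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(GlossjointError, ValueError):
    """An experimental design parameter is out of range or inconsistent."""


class ModelMismatchError(GlossjointError, ValueError):
    """Scales and model specification disagree (e.g. interaction terms
    requested by a full model but absent from the scales)."""


class InvalidParameterError(GlossjointError, ValueError):
    """A numeric parameter violates its constraint (e.g. sigma <= 0)."""


class DataError(GlossjointError, ValueError):
    """A trial table contains out-of-range levels or malformed entries."""


class NonNestedModelsError(GlossjointError, ValueError):
    """A likelihood-ratio test was requested for models that are not nested."""


class OptimizationError(GlossjointError, RuntimeError):
    """The maximum-likelihood optimizer failed to converge."""


class NormalizationError(GlossjointError, ValueError):
    """Scale normalization is undefined (all estimates zero)."""


class NonMonotoneScaleError(GlossjointError, ValueError):
    """A fitted perceptual scale is not monotone where monotonicity is
    required (equal-step stimulus selection)."""


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation: some maximum-likelihood
    estimates diverge and have been clamped."""
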