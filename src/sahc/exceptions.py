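"""Exception hierarchy for the sahc package."""


class SahcError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SahcError):
    """Centrifuge or body geometry is physically impossible."""


class UndefinedGradientError(SahcError):
    """G-gradient requested for a configuration with zero foot-level g."""


class EmptyInputError(SahcError):
    """An operation received an empty time series."""


class ChannelRejectedError(SahcError):
    """Channel failed the 95 % validity gate and must not be resampled."""


class InsufficientDataError(SahcError):
    """Too few valid samples to fit the interpolating spline."""


class ConfigurationError(SahcError):
    """Phase structure or pipeline configuration is inconsistent."""


class UnclassifiableRunError(SahcError):
    """A required channel is missing, so the run cannot be PSS-classified."""


class SchemaError(SahcError):
    """Input file does not match the expected schema."""


class RankDeficiencyError(SahcError):
    """Fixed-effect design matrix is rank deficient."""

    def __init__(self, message, collinear=()):
        super().__init__(message)
        self.collinear = tuple(collinear)


class NonNestedModelsError(SahcError):
    """Likelihood-ratio test requested for non-nested models."""


class ZeroVarianceError(SahcError):
    """Correlation undefined because one variable has zero variance."""
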