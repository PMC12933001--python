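"""Exception hierarchy for the ecglvh package."""


class EcgLvhError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EcgLvhError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(EcgLvhError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class FormatError(EcgLvhError, ValueError):
    """A file does not conform to the expected on-disk format."""


class UnitError(FormatError):
    """A physical unit cannot be converted to millivolts."""


class ExtractionError(EcgLvhError, RuntimeError):
    """Median-beat extraction failed (too few retained beats)."""

    def __init__(self, message: str, participant_id: str | None = None):
        super().__init__(message)
        self.participant_id = participant_id


class DegenerateFeatureError(EcgLvhError, ValueError):
    """A continuous feature is constant on the training split."""


class ImputationError(EcgLvhError, ValueError):
    """A column is entirely missing and cannot be imputed."""


class FitError(EcgLvhError, RuntimeError):
    """A statistical model could not be fitted."""


class UndefinedMetricError(EcgLvhError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


class DivergenceError(EcgLvhError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class GroupingError(EcgLvhError, ValueError):
    """Percentile grouping produced an empty or degenerate group."""
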