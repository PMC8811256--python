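"""Exception and warning types shared across the pipeline."""


class TrlimError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(TrlimError):
    """A weighing or phenotype record violates its invariants (e.g. nonpositive interval)."""


class InvalidInputError(TrlimError):
    """A scalar input is outside its documented domain."""


class UndefinedDivisionError(TrlimError):
    """A ratio is requested with a zero denominator."""


class RankDeficiencyError(TrlimError):
    """A least-squares design is singular; the message names the offending structure."""


class UnfittableError(TrlimError):
    """Too few or too degenerate data points for the requested model."""


class ParameterError(TrlimError):
    """A simulation or configuration parameter is outside its documented domain."""


class StageError(TrlimError):
    """A pipeline stage failed; the message names the stage."""


class TrlimWarning(UserWarning):
    """Base warning category."""


class MeasurementWarning(TrlimWarning):
    """Suspicious but tolerated measurement (negative transpiration, mass gain...)."""


class AnalysisWarning(TrlimWarning):
    """Non-fatal analysis condition (truncated variance component, dropped covariate...)."""
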