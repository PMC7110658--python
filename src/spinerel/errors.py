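"""Exception hierarchy.

Every distinct failure mode named in the module contracts maps to its own
exception class so callers (and tests) can discriminate without string
matching.
"""


class SpinerelError(Exception):
    """Base class for all package errors."""


class MissingColumnError(SpinerelError):
    """A required column is absent from a delimited input table."""


class UnknownTokenError(SpinerelError):
    """A tissue/mode/condition token is not one of the allowed values."""


class InvalidDistributionError(SpinerelError):
    """A distribution row violates its invariants (e.g. mean <= 0, std < 0)."""


class MissingEntryError(SpinerelError, KeyError):
    """A resistance/demand/area lookup found no matching entry."""


class DegenerateDistributionError(SpinerelError):
    """Both standard deviations are zero: the reliability index is undefined
    and failure reduces to the deterministic indicator mu_R <= mu_Q."""


class EmptySystemError(SpinerelError):
    """A series/parallel aggregation was asked for zero components."""


class EnumerationBoundError(SpinerelError):
    """An exact-enumeration oracle call exceeds its component-count bound."""


class CalibrationBracketError(SpinerelError):
    """The calibration target lies outside the bracketable range of the
    demand scale even after bracket expansion."""


class ProbabilityRangeError(SpinerelError, ValueError):
    """A probability argument lies outside [0, 1] (or (0, 1) where open)."""


class PipelineStageError(SpinerelError):
    """An error occurred inside a named pipeline stage; wraps the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
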