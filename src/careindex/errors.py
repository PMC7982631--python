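"""Exception hierarchy for the careindex pipeline.

Every stage raises a subclass of :class:`CareIndexError` so callers can
distinguish data problems (schema, vocabulary, domain) from usage problems
(insufficient or degenerate input) without string matching.
"""


class CareIndexError(Exception):
    """Base class for all careindex errors."""


class SchemaError(CareIndexError):
    """A required column is missing or the header does not match the dialect."""


class VocabularyError(CareIndexError):
    """A categorical label (measure, sex, age group, metric) is not recognised."""


class DomainError(CareIndexError):
    """A numeric value violates its domain (negative count, zero denominator...)."""


class IntegrityError(CareIndexError):
    """Duplicate (stratum, measure) rows or other internal inconsistency."""


class InsufficientDataError(CareIndexError):
    """Too few observations to fit or assemble the requested object."""


class DegenerateDataError(CareIndexError):
    """Input is structurally unusable (zero-variance index column, etc.)."""


class PairingError(CareIndexError):
    """Two records that must share a stratum key do not."""


class CoverageError(CareIndexError):
    """An aggregate was requested over strata that are not all present."""


class AlignmentError(CareIndexError):
    """Age keys of rate, structure and population inputs do not line up."""


class ConfigError(CareIndexError):
    """Invalid generator or pipeline configuration."""


class PipelineStageError(CareIndexError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
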