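"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`HRClassifyError`, so callers can distinguish validation failures
from programming errors.
"""


class HRClassifyError(ValueError):
    """Base class for all package errors."""


class MalformedInputError(HRClassifyError):
    """An input file or matrix violates its format contract."""


class DuplicateIdentifierError(HRClassifyError):
    """Gene or sample identifiers collide (e.g. after version stripping)."""


class MalformedAnnotationError(HRClassifyError):
    """A cytoband/annotation file violates its contract."""


class NoAnnotationError(HRClassifyError):
    """An operation requiring annotation received an empty table."""


class SchemaVersionError(HRClassifyError):
    """A serialized model bundle has an unsupported schema version."""


class MissingFieldError(HRClassifyError):
    """A serialized model bundle lacks a required field."""


class EmptyAfterFilterError(HRClassifyError):
    """A filtering step removed every gene."""


class DegenerateLibraryError(HRClassifyError):
    """A sample library is all-zero or has zero effective size."""


class ZeroVarianceError(HRClassifyError):
    """A gene has zero variance where standardization requires spread."""


class MissingStatisticsError(HRClassifyError):
    """Standardization statistics do not cover a requested gene."""


class ExcessiveMissingnessError(HRClassifyError):
    """Too many signature genes are absent from an input matrix."""


class UnmappedCellError(HRClassifyError):
    """A cell has no group assignment during pseudobulking."""


class DegenerateLabelsError(HRClassifyError):
    """Labels contain a single class where both are required."""


class StratificationError(HRClassifyError):
    """Cross-validation folds could not keep both classes present."""


class EmptySignatureError(HRClassifyError):
    """Differential expression selected no genes."""


class CannotFitTrendError(HRClassifyError):
    """Too few distinct means to fit the mean-variance trend."""


class RankDeficiencyError(HRClassifyError):
    """The design matrix is singular."""


class UndefinedCorrelationError(HRClassifyError):
    """Pearson correlation is undefined (constant input)."""


class UndefinedAUCError(HRClassifyError):
    """AUC is undefined because one class is absent."""
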