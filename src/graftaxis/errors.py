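"""Exception hierarchy.

Every failure mode of the pipeline raises a named subclass of
:class:`GraftAxisError` so callers can distinguish data problems
(duplicate identifiers, missing values) from configuration problems
(infeasible couplings, k larger than the point set).
"""


class GraftAxisError(Exception):
    """Base class for all graftaxis errors."""


# --- cohort_io ---------------------------------------------------------------

class DuplicateIdentifierError(GraftAxisError):
    """A gene, protein or sample identifier occurs more than once."""


class NonNumericCellError(GraftAxisError):
    """A matrix cell could not be parsed as a real number."""

    def __init__(self, row: str, col: str, value: object):
        self.row, self.col, self.value = row, col, value
        super().__init__(f"non-numeric cell at row {row!r}, column {col!r}: {value!r}")


class EmptyMatrixError(GraftAxisError):
    """The parsed matrix has no rows or no columns."""


class MissingValuesError(GraftAxisError):
    """A feature row contains missing entries where none are permitted."""


class MatrixTooSmallError(GraftAxisError):
    """Fewer features or samples than the type's minimum."""


class NoCommonSamplesError(GraftAxisError):
    """Expression, protein and clinical tables share no sample identifier."""


class AllProteinsRemovedError(GraftAxisError):
    """The variance filter would remove every protein."""


class InvalidClinicalValueError(GraftAxisError):
    """A clinical field violates its range (e.g. non-positive eGFR)."""


# --- synthetic_cohort --------------------------------------------------------

class InfeasibleCouplingError(GraftAxisError):
    """Requested rank-correlation targets are jointly unsatisfiable."""


class InvalidConfigError(GraftAxisError):
    """A synthetic-cohort or pipeline configuration violates an invariant."""


# --- gene_networks -----------------------------------------------------------

class NoReferenceGenesError(GraftAxisError):
    """No gene is positive in every sample; size factors are undefined."""


class TargetExceedsGenesError(GraftAxisError):
    """Variable-gene target count exceeds the number of genes."""


class ConstantRowError(GraftAxisError):
    """A gene row is constant and cannot be z-scored."""


class PerplexityTooLargeError(GraftAxisError):
    """t-SNE perplexity too large for the number of points."""


class KExceedsPointsError(GraftAxisError):
    """k-means cluster count exceeds the number of points."""


class EmptyNetworkError(GraftAxisError):
    """A network label set leaves some network without member genes."""


# --- cross_cohort ------------------------------------------------------------

class UnlabeledCommonGeneError(GraftAxisError):
    """A gene in the common set has no network label in one cohort."""


# --- serum_axes / signature_validation --------------------------------------

class TooFewPairsError(GraftAxisError):
    """Fewer than three complete observation pairs after pairwise deletion."""


class UnknownNetworkIdError(GraftAxisError):
    """An axis definition references a network id that does not exist."""


class UnknownProteinError(GraftAxisError):
    """A signature references a protein absent from the panel."""


class TooFewMembersError(GraftAxisError):
    """Intrasignature correlation needs at least two member proteins."""


class InsufficientProteinsError(GraftAxisError):
    """The panel is too small to draw the requested random sets."""


class UnknownVariableError(GraftAxisError):
    """A clinical association variable is absent from the clinical table."""


# --- pipeline ---------------------------------------------------------------

class StageFailureError(GraftAxisError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
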