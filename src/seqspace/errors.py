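"""Exception hierarchy.

Every error raised deliberately by seqspace derives from :class:`SeqspaceError`
so callers (and the CLI) can distinguish computation errors from bugs.
"""


class SeqspaceError(Exception):
    """Base class for all seqspace errors."""


class EmptyInputError(SeqspaceError):
    """An input file or alignment contained no usable records."""


class AlignmentShapeError(SeqspaceError):
    """Sequences in one alignment do not all have the same length."""


class DuplicateIdentifierError(SeqspaceError):
    """The same sequence identifier appears more than once."""


class MissingIdentifierError(SeqspaceError):
    """A requested identifier is not present in the alignment or space."""


class FormatError(SeqspaceError):
    """A file does not conform to the expected format dialect."""


class AnnotationConflictError(SeqspaceError):
    """An element is annotated with two different groups or colors."""


class UnsupportedScoringError(SeqspaceError):
    """The requested scoring cannot be applied to this alphabet."""


class MatrixUnavailableError(SeqspaceError):
    """A recognized substitution-matrix name with no embedded data."""


class AlignmentFrameError(SeqspaceError):
    """Active and supplementary alignments have different column counts."""


class InvalidDistanceMatrixError(SeqspaceError):
    """Distance matrix is not square/symmetric/zero-diagonal as required."""


class TooFewElementsError(SeqspaceError):
    """Fewer elements than the operation can meaningfully handle."""


class SpaceMismatchError(SeqspaceError):
    """Cross-distance columns do not match the active space's elements."""


class InvalidKError(SeqspaceError):
    """Cluster count outside the valid range for the data."""


class InvalidRangeError(SeqspaceError):
    """An empty or out-of-bounds K range."""


class InvalidAxisError(SeqspaceError):
    """Requested plot component does not exist in the space."""


class EmptyGroupError(SeqspaceError):
    """No annotated elements remain after intersecting ids with groups."""


class ChainExhaustionError(SeqspaceError):
    """More groups than available PDB chain identifiers."""
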