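"""Exception hierarchy shared across the package.

All domain errors derive from :class:`DeltaRankError` so callers can catch
one base class at pipeline boundaries (the CLI maps them to exit code 1).
"""


class DeltaRankError(Exception):
    """Base class for all errors raised by deltarank."""


class FormatError(DeltaRankError):
    """An on-disk file does not conform to its declared layout."""


class ValidationError(DeltaRankError):
    """An in-memory object violates a domain invariant."""


class EmptyNetworkError(DeltaRankError):
    """A background network ended up with zero edges."""


class DegenerateInputError(DeltaRankError):
    """An operation received an input too small for its statistic."""


class MissingGeneError(DeltaRankError):
    """A network edge references a gene absent from the expression matrix."""


class InsufficientCellsError(DeltaRankError):
    """A group comparison has fewer than two cells on one side."""
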