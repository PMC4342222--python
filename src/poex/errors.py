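"""Exception hierarchy shared across the package."""


class PoexError(Exception):
    """Base class for all package errors."""


class UsageError(PoexError, ValueError):
    """An argument violates a documented precondition."""


class PileupFormatError(PoexError):
    """A pileup file violates the TSV contract (malformed row, duplicate position)."""


class NormalizationError(PoexError):
    """Library-size normalization is undefined (e.g. a zero-total library)."""


class AnnotationError(PoexError):
    """A pileup position lacks a reference base annotation."""


class IntegrityError(PoexError):
    """Internal inconsistency between tables (e.g. a diagnostic SNP equal to the reference base)."""


class LowCoverageError(PoexError):
    """Coverage is too low for the requested operation."""


class DataError(PoexError):
    """Input data violate a stated invariant (e.g. expression below the floor)."""
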