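"""Exception hierarchy.

Fatal contract/format violations raise; recoverable per-line or per-row
problems are collected in counters/reports by the operation that met them.
"""


class ConceptvecError(Exception):
    """Base class for all package errors."""


class FormatError(ConceptvecError):
    """Unrecoverable problem with an input file's structure."""


class ContractViolation(ConceptvecError):
    """A precondition stated by the API was violated by the caller."""


class AbsentVectorError(ConceptvecError):
    """A token/term could not be resolved to any vector (not even subword)."""


class EmptySentenceError(ConceptvecError):
    """No token of a sentence survived preparation."""


class DegenerateProjectionError(ConceptvecError):
    """PCA projection requested on a rank-deficient point set."""
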