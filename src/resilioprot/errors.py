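"""Exception hierarchy for resilioprot.

Every error raised by the package derives from :class:`ResilioprotError`
so callers can catch pipeline failures with a single clause.
"""


class ResilioprotError(Exception):
    """Base class for all resilioprot errors."""


class FormatError(ResilioprotError):
    """A required column or field is missing or malformed."""


class AnnotationError(ResilioprotError):
    """A sample in the intensity matrix has no group annotation (or vice versa)."""


class DuplicateKeyError(ResilioprotError):
    """A protein accession appears more than once."""


class EmptyTableError(ResilioprotError):
    """An operation removed every protein from the table."""


class SpecError(ResilioprotError):
    """A synthetic-data specification is infeasible or out of domain."""


class ContractError(ResilioprotError):
    """An operation was called outside its stated precondition."""
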