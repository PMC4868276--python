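"""Exception hierarchy for parsing and contract violations."""


class AcetylsiteError(Exception):
    """Base class for all package errors."""


class FormatError(AcetylsiteError, ValueError):
    """A file did not conform to its declared dialect (names the offending line)."""


class SiteReferenceError(AcetylsiteError, KeyError):
    """A site annotation refers to an unknown protein identifier."""


class BoundsError(AcetylsiteError, IndexError):
    """A 1-based sequence position lies outside the protein."""


class NonLysineError(AcetylsiteError, ValueError):
    """A site annotation points at a residue that is not lysine."""


class AlignmentError(AcetylsiteError, ValueError):
    """A per-residue profile file does not match the sequence length."""


class ChannelMissingError(AcetylsiteError, KeyError):
    """An encoder requires a profile channel that was not provided."""


class ContractError(AcetylsiteError, ValueError):
    """A precondition of an operation was violated."""
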