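"""Exception hierarchy.

Parse errors (malformed input files) are kept distinct from validation
errors (well-formed input that violates a biological precondition, e.g. a
REF allele that does not match the reference sequence) and from coordinate
errors (asking for the CDS coordinate of a non-coding base).
"""


class MadwError(Exception):
    """Base class for all package errors."""


class ParseError(MadwError):
    """A record in an input file could not be parsed."""


class ValidationError(MadwError):
    """Input parsed but violates a precondition (e.g. REF/reference mismatch)."""


class CoordinateError(MadwError):
    """A genomic/CDS/protein coordinate request is out of domain."""
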