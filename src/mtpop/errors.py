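"""Exception hierarchy shared across the package.

Three error families map onto the three distinct nonzero CLI exit codes:
input that cannot be read (:class:`ParseError`), input that reads but
violates a model invariant (:class:`ValidationError`), and computations
whose numeric preconditions fail (:class:`NumericError`).
"""


class MtpopError(Exception):
    """Base class for all package-raised errors."""

    exit_code = 1


class ParseError(MtpopError):
    """Malformed input text (bad token, bad table layout, bad Newick)."""

    exit_code = 3


class ValidationError(MtpopError):
    """Structurally valid input that violates a domain invariant."""

    exit_code = 4


class NumericError(MtpopError):
    """A statistic's numeric precondition is not met (e.g. n < 2)."""

    exit_code = 5
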