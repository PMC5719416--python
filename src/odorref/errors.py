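"""Exception hierarchy, mapped to CLI exit codes.

Validation problems (bad configuration, violated preconditions) exit with 2,
numerical failures (rank deficiency, ill-conditioning) with 3, and I/O
problems with 4.
"""


class OdorrefError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(OdorrefError):
    """A precondition or configuration constraint was violated."""

    exit_code = 2


class NumericalError(OdorrefError):
    """A computation failed for numerical reasons (rank, conditioning)."""

    exit_code = 3


class InputOutputError(OdorrefError):
    """A file could not be read or written."""

    exit_code = 4
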