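"""Exception hierarchy.

Exit-code mapping used by the CLI: validation errors -> 1, numerical
errors -> 2.
"""


class PlaqsegError(Exception):
    """Base class for package errors."""


class ValidationError(PlaqsegError):
    """Invalid inputs: inconsistent shapes, bad parameters, missing data."""


class DegenerateInputError(ValidationError):
    """Structurally valid input on which the operation is undefined
    (zero-variance ROI, empty mask, empty table)."""


class NumericalError(PlaqsegError):
    """Numerical failure: singular covariance, non-convergence."""


class FormatError(PlaqsegError):
    """Unreadable or unsupported on-disk format."""
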