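"""Exception hierarchy shared by all pipeline stages.

Each error class carries the CLI exit code the umbrella application uses:
0 success, 2 validation, 3 format, 4 internal consistency.
"""


class PharmaboostError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class ValidationError(PharmaboostError):
    """Inputs violate a documented precondition (bad config, missing truth entry...)."""

    exit_code = 2


class FormatError(PharmaboostError):
    """A file does not conform to its declared dialect or schema."""

    exit_code = 3


class ConsistencyError(PharmaboostError):
    """Internal invariant violated (e.g. a negative 2x2 cell)."""

    exit_code = 4
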