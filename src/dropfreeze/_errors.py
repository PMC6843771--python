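"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation problems exit 2,
undefined statistics (e.g. a median that does not exist because fewer
than half the droplets froze) exit 3.
"""


class DropfreezeError(Exception):
    """Base class for all package errors."""


class FormatError(DropfreezeError):
    """A file does not conform to the expected schema."""


class ValidationError(DropfreezeError):
    """An input value violates a documented precondition or invariant."""


class UndefinedStatisticError(DropfreezeError):
    """The requested statistic does not exist for the given data."""
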