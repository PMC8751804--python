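"""Exception hierarchy for input validation.

Each class maps to one rule of the input contract so callers (and the CLI's
exit codes) can tell a malformed file from a physically implausible one.
"""


class H2SIndexError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(H2SIndexError):
    """A CSV cell could not be parsed (timestamp or concentration)."""


class IrregularIntervalError(H2SIndexError):
    """Consecutive timestamps deviate from the regular logging interval."""

    def __init__(self, message: str, gaps=None):
        super().__init__(message)
        #: list of (row_index, gap_seconds) for the offending transitions
        self.gaps = list(gaps or [])


class NegativeReadingError(H2SIndexError):
    """A concentration reading is negative (sensor drift must be fixed upstream)."""


class InfeasibleScenario(H2SIndexError):
    """A synthetic scenario cannot be realised (tasks do not fit in the shift)."""
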