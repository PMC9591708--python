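"""Exception hierarchy shared across the package."""


class ThermocleanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ThermocleanError):
    """A file's structure (columns, header) is not usable."""


class RowParseError(ThermocleanError):
    """A data row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ValidationError(ThermocleanError):
    """Inputs violate a documented precondition or invariant."""


class DegenerateInputError(ThermocleanError):
    """Numerically degenerate input (e.g. repeated times in a slope fit)."""


class UndefinedMetricError(ThermocleanError):
    """A derived measure is undefined for the given inputs (e.g. zero retained readings)."""


class InfeasibleDesignError(ThermocleanError):
    """A study-design request can never be satisfied (e.g. delta <= |mu|)."""
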