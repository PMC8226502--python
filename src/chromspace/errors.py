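"""Exception hierarchy for chromspace.

All package-specific failures derive from :class:`ChromspaceError` so callers
(and the CLI) can catch one base class and translate it into a non-zero exit.
"""


class ChromspaceError(Exception):
    """Base class for all chromspace errors."""


class InvalidParameterError(ChromspaceError, ValueError):
    """A physical parameter is non-finite or outside its valid domain."""


class InputError(ChromspaceError, ValueError):
    """Malformed user input: bad run tables, duplicate entries, bad ranges."""


class ParseError(InputError):
    """A file could not be parsed; carries a line number where possible."""


class UnretainedSoluteError(ChromspaceError):
    """A solute elutes at (or before) the dead time and cannot be fitted."""


class FitFailureError(ChromspaceError):
    """Retention-parameter inversion failed (no root in the search bracket)."""

    def __init__(self, message: str, compound_id: str | None = None):
        super().__init__(message)
        self.compound_id = compound_id


class InterpolationError(ChromspaceError):
    """A (T, pH) query needs an unfitted calibration corner."""


class RangeError(ChromspaceError, ValueError):
    """A query lies outside the calibrated range plus the allowed margin."""


class NoDesignSpaceError(ChromspaceError):
    """No grid node meets the resolution criterion."""


class UndefinedResultError(ChromspaceError):
    """The requested quantity is undefined (e.g. resolution of < 2 peaks)."""


class QuantitationError(ChromspaceError):
    """Peak areas cannot be corrected (e.g. a response factor is missing)."""


class ExtrapolationWarning(UserWarning):
    """A (T, pH) query is outside the calibrated range but within the margin."""
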