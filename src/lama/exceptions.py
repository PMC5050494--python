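"""Exception hierarchy for localization-data handling and analysis."""


class LamaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LamaError):
    """The file does not match any known localization-table dialect."""


class SchemaError(LamaError):
    """A mandatory column (x, y or frame) is missing from the input."""


class ParseError(LamaError):
    """A cell could not be parsed as a number.

    Carries the 0-based data row index in ``row``.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EstimationError(LamaError):
    """An estimator could not produce a result (degenerate geometry, too few data)."""


class FitError(LamaError):
    """A nonlinear fit failed to converge; ``diagnostics`` holds solver output."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class MatchingError(LamaError):
    """No fiducial pairs could be matched between channels."""
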