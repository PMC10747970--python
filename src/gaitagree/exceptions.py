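"""Exception hierarchy shared by all analysis stages."""


class GaitAgreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GaitAgreeError):
    """Input table is missing a required column or has an unusable layout."""


class ParseError(GaitAgreeError):
    """A value in the input could not be parsed.

    Attributes
    ----------
    row : int or None
        1-based row number in the source file (header counts as row 1).
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DegenerateSeriesError(GaitAgreeError):
    """Too few complete (reference, test) pairs for any downstream fit."""


class DegenerateInputError(GaitAgreeError):
    """Input is constant or otherwise unusable for a statistical test."""


class DegenerateFitError(GaitAgreeError):
    """Regression cannot be estimated (e.g. too few finite pairwise slopes)."""


class CIUndefinedError(GaitAgreeError):
    """Sample too small for rank-based confidence bounds at the requested level.

    Attributes
    ----------
    partial
        The fit result with point estimates filled in and NaN confidence
        bounds, so callers can still report the estimates.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class GenerationError(GaitAgreeError):
    """Synthetic-data generation failed (e.g. truncation retries exhausted)."""
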