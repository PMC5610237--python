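"""Exception hierarchy for the :mod:`twonn` package.

All errors raised by the library derive from :class:`TwoNNError`, which itself
derives from :class:`ValueError` so that generic callers can catch either.
"""


class TwoNNError(ValueError):
    """Base class for all twonn errors."""


class InvalidParameterError(TwoNNError):
    """A parameter is outside its admissible range (e.g. nonpositive count)."""


class InsufficientDataError(TwoNNError):
    """Too few points for the requested operation (fewer than 3, or fewer
    than 2 after discarding)."""


class DuplicatePointsError(TwoNNError):
    """Coincident points produce r1 = 0, making mu = r2/r1 undefined."""


class InvalidMatrixError(TwoNNError):
    """A distance matrix violates symmetry, nonnegativity or zero-diagonal."""


class DegenerateFitError(TwoNNError):
    """The origin-constrained fit is undefined (all abscissae zero)."""


class ParseError(TwoNNError):
    """A delimited text file could not be parsed as a numeric table."""
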