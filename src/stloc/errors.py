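"""Typed exceptions shared across the package.

Degenerate statistics and geometry raise rather than returning silent
zeros: a silent 0 would corrupt downstream gene rankings.
"""


class StlocError(Exception):
    """Base class for all package errors."""


class ValidationError(StlocError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(StlocError, ValueError):
    """A file does not match its declared format."""


class DegenerateGeometryError(ValidationError):
    """Coordinate geometry with zero range on an axis (min-max undefined)."""


class UndefinedStatisticError(StlocError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class TrainingError(StlocError, RuntimeError):
    """Optimization failed (e.g. loss became non-finite)."""
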