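"""Exception hierarchy shared across the package."""


class PlastpopError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlastpopError, ValueError):
    """Malformed input file (duplicate IDs, missing columns, empty file)."""


class AlignmentError(PlastpopError, ValueError):
    """Sequences that do not form a valid alignment (unequal lengths, empty)."""


class SpecError(PlastpopError, ValueError):
    """Invalid simulation specification (overlapping intervals, bad rates)."""


class UndefinedStatisticError(PlastpopError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. n < 2, Ht = 0)."""
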