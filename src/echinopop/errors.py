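"""Exception hierarchy used across the package."""


class PopgenError(Exception):
    """Base class for all package errors."""


class AlignmentError(PopgenError):
    """Sequences are not a consistent alignment (length mismatch, bad symbol)."""


class PopulationMapError(PopgenError):
    """A sample, population or region is missing from the population map."""


class GenePopFormatError(PopgenError):
    """GenePop file violates the 3-digit dialect expected here."""


class ValidationError(PopgenError):
    """A carrier's invariant is violated (asymmetry, negative distance, ...)."""


class UndefinedStatisticError(PopgenError):
    """The requested statistic is undefined for the given input (e.g. n < 2)."""
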