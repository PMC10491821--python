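"""Exception hierarchy for hatchsex.

All package errors derive from :class:`HatchsexError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""


class HatchsexError(Exception):
    """Base class for all hatchsex errors."""


class InvalidConfigError(HatchsexError, ValueError):
    """A configuration object violates its invariants."""


class DomainError(HatchsexError, ValueError):
    """An input value is outside the mathematical domain (e.g. concentration <= 0)."""


class InsufficientDataError(HatchsexError, ValueError):
    """Too few observations to perform the requested computation."""


class DegenerateDataError(HatchsexError, ValueError):
    """Data with zero spread; the requested fit is not identifiable."""


class UnstableFitError(HatchsexError, RuntimeError):
    """Bootstrap refits failed too often to yield trustworthy intervals."""


class FitError(HatchsexError, RuntimeError):
    """A nonlinear fit failed to converge."""


class OrientationError(HatchsexError, ValueError):
    """Female and male distributions are not ordered as expected (female mode < male mode)."""


class SearchRangeError(HatchsexError, ValueError):
    """No threshold satisfying the requested certainty exists inside the search range."""


class PairingError(HatchsexError, ValueError):
    """Paired records are incomplete or inconsistent."""


class DesignError(HatchsexError, ValueError):
    """The experimental design does not support the requested analysis (e.g. single-sex data)."""


class OutOfRangeError(HatchsexError, ValueError):
    """A response value lies outside the invertible range of the calibration curve."""


class SchemaError(HatchsexError, ValueError):
    """A tabular input is missing required columns or contains invalid rows."""


class UndefinedCVError(HatchsexError, ZeroDivisionError):
    """Coefficient of variation is undefined (zero mean)."""
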