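"""Exceptions and warning categories used across the package."""


class SewerCH4Error(Exception):
    """Base class for all package errors."""


class InvalidInputError(SewerCH4Error, ValueError):
    """An input violates a precondition (non-finite, negative, unsorted ...)."""


class NoSolutionError(SewerCH4Error, ValueError):
    """The shear-stress inversion has no real root at the requested stress."""


class NoPhysicalSolutionError(NoSolutionError):
    """Real roots exist but none corresponds to a non-negative velocity."""


class InconsistentEPSError(SewerCH4Error, ValueError):
    """EPS mass exceeds the total biofilm mass it should be subtracted from."""


class InvalidBiomassError(SewerCH4Error, ValueError):
    """A negative microorganism amount was fed to the methane model."""


class DegenerateFitError(SewerCH4Error, ValueError):
    """The design matrix is rank deficient (too few distinct shear values)."""


class LookupError_(SewerCH4Error, KeyError):
    """Unknown taxon or condition label in an abundance table."""


class UndefinedChangeError(SewerCH4Error, ZeroDivisionError):
    """Relative change from a zero baseline abundance."""


class CalibrationWarning(UserWarning):
    """Inputs outside the hydraulic calibration envelope (extrapolation)."""


class ModelValidityWarning(UserWarning):
    """A fitted empirical form was evaluated outside its validity range."""


class NormalizationWarning(UserWarning):
    """An abundance column does not sum to 100% within tolerance."""
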