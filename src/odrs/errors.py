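"""Exception hierarchy shared across the screening pipeline."""


class OdrsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(OdrsError):
    """A file does not match the documented dialect (missing/unknown columns)."""


class ValidationError(OdrsError):
    """A record violates an invariant (negative intensity, bad role, ...)."""


class DegenerateControlError(OdrsError):
    """Control wells cannot anchor a normalization (zero/negative mean)."""


class NoGrowthError(OdrsError):
    """Negative controls did not grow above baseline; GR values undefined."""


class DomainError(OdrsError):
    """An argument is outside the mathematical domain of the operation."""


class GridError(OdrsError):
    """Concentration grids are non-increasing, mismatched, or too short."""


class InsufficientDataError(OdrsError):
    """Too few observations to compute the requested quantity."""


class DegenerateRangeError(OdrsError):
    """Min-max normalization is undefined because all values coincide."""


class DegenerateLabelsError(OdrsError):
    """Only one outcome class is present; discrimination is undefined."""


class UndefinedTestError(OdrsError):
    """A statistical test's requirements are unmet (e.g. zero events)."""
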