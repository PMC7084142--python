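"""Exception hierarchy shared across the package."""


class CryoalgaeError(ValueError):
    """Base class for all domain errors raised by cryoalgae."""


class InvalidMeasurementError(CryoalgaeError):
    """A fluorescence measurement violates a physical precondition."""


class InsufficientDataError(CryoalgaeError):
    """Too few usable observations to fit or summarize."""


class DegenerateCurveError(CryoalgaeError):
    """A light-response curve carries no fittable signal."""


class RankDeficiencyError(CryoalgaeError):
    """Regression design has no spread in the predictor."""


class GridError(CryoalgaeError):
    """Wavelength grids are incompatible or a range falls off-grid."""


class ForcingError(CryoalgaeError):
    """Environmental forcing series is incomplete or malformed."""


class OpticsError(CryoalgaeError):
    """Ice-column optical properties are missing or unphysical."""
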