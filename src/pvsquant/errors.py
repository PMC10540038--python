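"""Exception hierarchy for pvsquant."""


class PvsQuantError(Exception):
    """Base class for all pvsquant errors."""


class ShapeError(PvsQuantError):
    """Image has the wrong dimensionality or mismatched grids."""


class SchemaError(PvsQuantError):
    """Tabular input is missing required columns."""


class ParameterError(PvsQuantError, ValueError):
    """A parameter violates its contract (negative radius, sigma < 0, ...)."""


class GeometryError(PvsQuantError):
    """Scene geometry is invalid (tube outside grid, degenerate spacing)."""


class DegenerateRoiError(PvsQuantError):
    """Analysis region is empty or otherwise unusable."""


class DegenerateMapError(PvsQuantError):
    """Vesselness map cannot be standardized (zero IQR, too few positives)."""


class CollinearityError(PvsQuantError):
    """Design matrix is rank deficient."""


class InsufficientDataError(PvsQuantError):
    """Not enough observations for the requested computation."""


class UndefinedCorrelationError(PvsQuantError):
    """Correlation is undefined because one variable is constant."""


class ConvergenceError(PvsQuantError):
    """A model fit failed to converge."""
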