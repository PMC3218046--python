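"""Exception hierarchy.

Everything raised deliberately by the library derives from :class:`FretlinError`
so the CLI can catch one type, print a one-line diagnostic and exit nonzero.
"""


class FretlinError(Exception):
    """Base class for all fretlin errors."""


class InvalidParameterError(FretlinError, ValueError):
    """A model parameter violates its domain (e.g. non-positive Michaelis constant)."""


class DegenerateParameterError(FretlinError, ValueError):
    """Parameters make the problem ill-posed (e.g. no enzyme flux at all)."""


class RegimeInconsistencyError(FretlinError):
    """A closed-form limit steady state falls outside [0, P_TOT]: the assumed
    operating regime cannot hold for these parameters."""


class ConvergenceError(FretlinError, RuntimeError):
    """An iterative solver exhausted its step budget."""


class DegenerateGridError(FretlinError, ValueError):
    """Too few distinct abscissa values for a meaningful fit."""


class DegenerateSeriesError(DegenerateGridError):
    """A measurement series cannot support a line fit."""


class CalibrationError(FretlinError, ValueError):
    """Unusable calibration endpoints (F_act == F_in), or a deliberately
    refused non-linear observable."""


class OutOfRangeError(FretlinError, ValueError):
    """A value lies outside its admissible range."""


class GridMismatchError(FretlinError, ValueError):
    """A wavelength is off the 5 nm emission-scan grid."""


class MalformedTableError(FretlinError, ValueError):
    """A CSV table does not follow the expected dialect."""


class DesignError(FretlinError, ValueError):
    """An internally inconsistent synthetic mixture design."""
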