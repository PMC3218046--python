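"""Linear calibration of the active-probe fraction.

If the FRET observable F is affine in the fraction of FRET-capable probes —
true for tau_mix and R_alt, false for the conventional ratio R — then readings
of the fully active and fully inactive probe (F_act, F_in; obtained e.g. with
saturating inhibitor doses) calibrate any intermediate reading:

    phi_a = (F_mix - F_in) / (F_act - F_in).

The estimator is affine-invariant and works identically for increasing and
decreasing observables.  For R the premise fails, so `active_fraction`
refuses ratio-R input unless explicitly overridden, in which case the biased
naive interpolation is used and the bias is the caller's to own.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CalibrationError, InvalidParameterError, OutOfRangeError
from .ratiometric import naive_fraction_from_R

__all__ = ["CalibrationPair", "active_fraction", "invert_linear_observable"]


@dataclass(frozen=True)
class CalibrationPair:
    """Observable readings with all probes active (F_act) and inactive (F_in)."""

    F_act: float
    F_in: float

    def __post_init__(self) -> None:
        if self.F_act == self.F_in:
            raise CalibrationError("degenerate calibration: F_act equals F_in")


def active_fraction(
    F_mix: float,
    cal: CalibrationPair,
    clamp_band: float = 0.02,
    observable: str | None = None,
    allow_nonlinear: bool = False,
) -> float:
    """Fraction of active probes from a linear FRET observable.

    ``F_mix`` may overshoot the calibration interval by at most ``clamp_band``
    (as a fraction of the interval) to absorb endpoint measurement noise; the
    result is clamped into [0, 1].  Larger overshoots raise
    :class:`OutOfRangeError`.

    ``observable`` may name the measurement ("tau", "R_alt", "R").  The
    conventional ratio "R" is refused — it is not affine in the active
    fraction, so linear interpolation is biased — unless
    ``allow_nonlinear=True``, which routes through the deliberately biased
    naive estimator.
    """
    if clamp_band < 0:
        raise InvalidParameterError("clamp_band must be non-negative")
    if observable == "R" and not allow_nonlinear:
        raise CalibrationError(
            "the conventional ratio R is not linear in the active fraction; "
            "use tau_mix or R_alt, or set allow_nonlinear=True to accept the bias"
        )
    if observable == "R":
        phi = naive_fraction_from_R(F_mix, cal.F_act, cal.F_in)
    else:
        phi = (F_mix - cal.F_in) / (cal.F_act - cal.F_in)
    if phi < -clamp_band or phi > 1.0 + clamp_band:
        raise OutOfRangeError(
            f"F_mix = {F_mix:g} maps to phi_a = {phi:.4f}, beyond the "
            f"calibration interval by more than the {clamp_band:g} clamp band"
        )
    return min(max(phi, 0.0), 1.0)


def invert_linear_observable(slope: float, intercept: float, observable_value: float) -> float:
    """Invert a fitted line observable = intercept + slope * phi_F.

    Equivalent to :func:`active_fraction` with calibration endpoints
    ``F_in = intercept`` and ``F_act = intercept + slope``.
    """
    if slope == 0:
        raise CalibrationError("zero slope: observable carries no fraction information")
    return (observable_value - intercept) / slope
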