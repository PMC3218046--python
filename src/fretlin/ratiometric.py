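"""Forward models of ratiometric FRET and the two ratio estimators.

Under donor excitation, N_D* excited donors either fluoresce or transfer
energy to the acceptor; the *apparent fraction of FRETing molecules* is
E*phi_F, the per-molecule FRET efficiency E times the fraction phi_F of
probes in the FRET-competent state.  The channel components are

    I_DD = g_D N_D* (1 - E phi_F) f_DD          donor emission, donor channel
    I_AD = g_A N_D* (1 - E phi_F) f_AD          donor crosstalk, acceptor channel
    I_AA = g_A (N_D* E phi_F + N_A^direct) f_AA acceptor emission (FRET + direct)
    I_DA = g_D (N_D* E phi_F + N_A^direct) f_DA acceptor into donor channel, ~0

The conventional ratio R = I_A^don / I_D^don is *non-linear* in phi_F (the
denominator itself carries the FRET response), while the alternative ratio

    R_alt = I_D^don / I_A^acc

(donor channel over the directly excited acceptor channel) is affine in
phi_F with negative slope — the property that makes linear calibration of
the active-probe fraction possible.  `naive_fraction_from_R` quantifies the
bias incurred by linearly interpolating R anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, InvalidParameterError, OutOfRangeError
from .spectra import CoverageFractions

__all__ = [
    "FretState",
    "ExcitationState",
    "ChannelIntensities",
    "channel_intensities",
    "ratio_R",
    "ratio_R_alt",
    "r_surface",
    "naive_fraction_from_R",
]


@dataclass(frozen=True)
class FretState:
    """Per-molecule FRET efficiency E and FRET-capable fraction phi_F."""

    E: float
    phi_F: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.E <= 1.0):
            raise InvalidParameterError("E must lie in [0, 1]")
        if not (0.0 <= self.phi_F <= 1.0):
            raise InvalidParameterError("phi_F must lie in [0, 1]")

    @property
    def apparent_fraction(self) -> float:
        """E * phi_F, the apparent fraction of FRETing molecules."""
        return self.E * self.phi_F


@dataclass(frozen=True)
class ExcitationState:
    """Excited-molecule counts per exposure and per-channel detector gains.

    N_D_star : donors excited under donor excitation
    N_A_direct : acceptors directly excited at the donor wavelength (usually ~0)
    N_A_acc : acceptors excited under the dedicated acceptor-excitation exposure
    gain_D, gain_A : multiplicative detector gains of the two channels
    """

    N_D_star: float
    N_A_direct: float = 0.0
    N_A_acc: float = 0.0
    gain_D: float = 1.0
    gain_A: float = 1.0

    def __post_init__(self) -> None:
        for name in ("N_D_star", "N_A_direct", "N_A_acc", "gain_D", "gain_A"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ChannelIntensities:
    """All channel components for one probe state (arbitrary digital units)."""

    I_DD: float
    I_DA: float
    I_AA: float
    I_AD: float
    I_A_acc: float

    @property
    def I_D_don(self) -> float:
        """Donor-channel intensity under donor excitation."""
        return self.I_DD + self.I_DA

    @property
    def I_A_don(self) -> float:
        """Acceptor-channel intensity under donor excitation."""
        return self.I_AA + self.I_AD


def channel_intensities(
    state: FretState, exc: ExcitationState, cov: CoverageFractions
) -> ChannelIntensities:
    """Forward model mapping a FRET state to the four channel components plus
    the direct acceptor-excitation intensity.  Linear in N_D_star."""
    x = state.apparent_fraction
    donors_emitting = exc.N_D_star * (1.0 - x)
    acceptors_emitting = exc.N_D_star * x + exc.N_A_direct
    return ChannelIntensities(
        I_DD=exc.gain_D * donors_emitting * cov.f_DD,
        I_DA=exc.gain_D * acceptors_emitting * cov.f_DA,
        I_AA=exc.gain_A * acceptors_emitting * cov.f_AA,
        I_AD=exc.gain_A * donors_emitting * cov.f_AD,
        I_A_acc=exc.gain_A * exc.N_A_acc * cov.f_AA,
    )


def ratio_R(
    state: FretState,
    exc: ExcitationState,
    cov: CoverageFractions,
    include_direct: bool = False,
) -> float:
    """Conventional ratio R = I_A^don / I_D^don.

    With ``include_direct=False`` (the usual assumption that direct acceptor
    excitation at the donor wavelength is negligible), and unit gains and
    f_DA = 0, this reduces to

        R = [E phi_F f_AA + (1 - E phi_F) f_AD] / [(1 - E phi_F) f_DD].
    """
    if not include_direct:
        exc = ExcitationState(exc.N_D_star, 0.0, exc.N_A_acc, exc.gain_D, exc.gain_A)
    ch = channel_intensities(state, exc, cov)
    if ch.I_D_don == 0:
        raise OutOfRangeError(
            "donor channel is zero (E*phi_F = 1 or f_DD = 0): R undefined"
        )
    return ch.I_A_don / ch.I_D_don


def ratio_R_alt(state: FretState, exc: ExcitationState, cov: CoverageFractions) -> float:
    """Alternative ratio R_alt = I_D^don / I_A^acc.

    The denominator is the directly excited acceptor intensity — a pure
    probe-count normalizer with no FRET dependence — so R_alt is affine in
    phi_F: R_alt = g_D N_D* (1 - E phi_F) f_DD / (g_A N_A^acc f_AA).
    """
    ch = channel_intensities(state, exc, cov)
    if ch.I_A_acc == 0:
        raise OutOfRangeError("direct acceptor excitation intensity is zero: R_alt undefined")
    return ch.I_D_don / ch.I_A_acc


def r_surface(
    e_phi_grid: np.ndarray,
    crosstalk_grid: np.ndarray,
    f_AA_over_f_DD: float = 1.0,
) -> np.ndarray:
    """Ratio surface R(E phi_F, f_AD/f_DD) under negligible direct excitation.

    Returns a matrix with rows indexed by the apparent FRETing fraction and
    columns by the donor-into-acceptor crosstalk ratio.  For E phi_F > 0 the
    surface increases along both axes and is convex along the E phi_F axis —
    the geometry behind the inherent non-linearity of R.
    """
    x = np.asarray(e_phi_grid, dtype=float)
    ct = np.asarray(crosstalk_grid, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise OutOfRangeError("E*phi_F grid must stay within [0, 1)")
    if np.any(ct < 0):
        raise OutOfRangeError("crosstalk grid must be non-negative")
    X = x[:, None]
    return (X * f_AA_over_f_DD + (1.0 - X) * ct[None, :]) / (1.0 - X)


def naive_fraction_from_R(R_mix: float, R_act: float, R_in: float) -> float:
    """Linear interpolation of the conventional ratio between its calibration
    endpoints: (R_mix - R_in) / (R_act - R_in).

    Returns the true phi_F only when R is affine in phi_F — which it is not
    for E > 0 — so this estimator is biased by construction; it exists to
    make that bias measurable.
    """
    if R_act == R_in:
        raise CalibrationError("degenerate calibration: R_act equals R_in")
    return (R_mix - R_in) / (R_act - R_in)
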