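"""Lifetime-based FRET quantification.

An excited donor relaxes by fluorescence (rate k_f) or, when an acceptor is
in range, by energy transfer (rate k_et).  The FRET efficiency is

    E = k_et / (k_f + k_et) = 1 - tau_f / tau,

with tau = 1/k_f the donor-only lifetime and tau_f = 1/(k_f + k_et) the
lifetime in the presence of acceptor.  For a two-population mixture in which
a fraction phi_F of donors is FRET-capable, the measured lifetime is the
fractionally weighted average of the components:

    E_mix = E * phi_F,     tau_mix = tau * (1 - E * phi_F),

i.e. tau_mix is affine in phi_F with slope -tau*E and intercept tau, which is
what makes FLIM titrations linear and invertible.  The module also provides a
frequency-domain (phase) lifetime simulator used to audit when the
weighted-average assumption holds: the phase estimator mixes components
through their complex demodulation responses, not their lifetimes, so it
deviates from the weighted average at high efficiency or modulation
frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSeriesError,
    InvalidParameterError,
    OutOfRangeError,
)

__all__ = [
    "LifetimeParams",
    "MixtureLifetime",
    "FrequencyDomainSettings",
    "MeasurementSeries",
    "LinearFit",
    "efficiency_from_lifetimes",
    "mixture_lifetime",
    "simulate_phase",
    "phase_lifetime",
    "phase_mixture_discrepancy",
    "fit_linearity",
]


@dataclass(frozen=True)
class LifetimeParams:
    """Donor lifetime tau_D (ns) and per-molecule FRET efficiency E.

    Equivalently parameterized by rate constants: k_f = 1/tau_D is the total
    donor de-excitation rate without acceptor, k_et the energy-transfer rate,
    with E = k_et/(k_f + k_et) and tau_f = 1/(k_f + k_et).
    """

    tau_D: float
    E: float

    def __post_init__(self) -> None:
        if self.tau_D <= 0:
            raise InvalidParameterError("tau_D must be positive")
        if not (0.0 <= self.E < 1.0):
            raise InvalidParameterError("E must lie in [0, 1)")

    @classmethod
    def from_rates(cls, k_f: float, k_et: float) -> "LifetimeParams":
        """Construct from rate constants in 1/ns."""
        if k_f <= 0 or k_et < 0:
            raise InvalidParameterError("need k_f > 0 and k_et >= 0")
        return cls(tau_D=1.0 / k_f, E=k_et / (k_f + k_et))

    @property
    def k_f(self) -> float:
        return 1.0 / self.tau_D

    @property
    def k_et(self) -> float:
        return self.k_f * self.E / (1.0 - self.E)

    @property
    def tau_f(self) -> float:
        """Lifetime of the FRET-capable species, tau_D * (1 - E), ns."""
        return self.tau_D * (1.0 - self.E)


@dataclass(frozen=True)
class MixtureLifetime:
    """Measured lifetime and overall efficiency of a two-population mixture."""

    tau_mix: float
    E_mix: float


@dataclass(frozen=True)
class FrequencyDomainSettings:
    """Frequency-domain FLIM acquisition settings.

    modulation_frequency in Hz; reference_lifetime in ns (fluorescein
    standard, 4.0 ns).
    """

    modulation_frequency: float = 40e6
    reference_lifetime: float = 4.0

    def __post_init__(self) -> None:
        if self.modulation_frequency <= 0:
            raise InvalidParameterError("modulation frequency must be positive")

    @property
    def omega(self) -> float:
        """Angular modulation frequency in rad/ns."""
        return 2.0 * math.pi * self.modulation_frequency * 1e-9


@dataclass(frozen=True)
class MeasurementSeries:
    """(fraction, observable) pairs from a mixture titration.

    ``observable`` names what was measured: "tau" (ns), "R_alt" or "R".
    """

    fractions: np.ndarray
    observables: np.ndarray
    noise_sd: float = 0.0
    observable: str = "tau"

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        obs = np.asarray(self.observables, dtype=float)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "observables", obs)
        if fr.shape != obs.shape:
            raise InvalidParameterError("fractions and observables must match in length")
        if fr.size and (fr.min() < 0 or fr.max() > 1):
            raise InvalidParameterError("fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")


@dataclass(frozen=True)
class LinearFit:
    """OLS line through a titration series; E_estimate = -slope/intercept for
    lifetime series (None otherwise)."""

    slope: float
    intercept: float
    r_squared: float
    E_estimate: float | None = None


def efficiency_from_lifetimes(tau: float, tau_f: float) -> float:
    """FRET efficiency from lifetimes without/with acceptor:
    E = (tau - tau_f)/tau."""
    if tau <= 0:
        raise InvalidParameterError("tau must be positive")
    if tau_f < 0:
        raise InvalidParameterError("tau_f must be non-negative")
    if tau_f > tau:
        raise OutOfRangeError(
            f"tau_f = {tau_f:g} exceeds tau = {tau:g}: negative efficiency"
        )
    return (tau - tau_f) / tau


def mixture_lifetime(params: LifetimeParams, phi_F: float) -> MixtureLifetime:
    """Fraction-weighted mixture lifetime: E_mix = E*phi_F and
    tau_mix = tau_D*(1 - E*phi_F)."""
    if not (0.0 <= phi_F <= 1.0):
        raise InvalidParameterError("phi_F must lie in [0, 1]")
    e_mix = params.E * phi_F
    return MixtureLifetime(tau_mix=params.tau_D * (1.0 - e_mix), E_mix=e_mix)


def simulate_phase(
    lifetimes: float | Sequence[float],
    fractions: float | Sequence[float] | None,
    settings: FrequencyDomainSettings,
) -> float:
    """Phase shift (radians) of the demodulated emission of a lifetime mixture.

    Each mono-exponential component contributes the complex response
    1/(1 + i*omega*tau); components are weighted by their *emitted photon*
    fraction, i.e. molecular fraction times lifetime, since steady-state
    brightness scales with lifetime.  For a single lifetime the phase is
    arctan(omega*tau).
    """
    taus = np.atleast_1d(np.asarray(lifetimes, dtype=float))
    if np.any(taus <= 0):
        raise InvalidParameterError("lifetimes must be positive")
    if fractions is None:
        fracs = np.ones_like(taus)
    else:
        fracs = np.atleast_1d(np.asarray(fractions, dtype=float))
    if fracs.shape != taus.shape or np.any(fracs < 0) or fracs.sum() == 0:
        raise InvalidParameterError("fractions must be non-negative and match lifetimes")
    w = fracs * taus  # photon weighting
    wt = settings.omega * taus
    g = np.sum(w / (1.0 + wt**2))
    s = np.sum(w * wt / (1.0 + wt**2))
    return float(math.atan2(s, g))


def phase_lifetime(phase: float, settings: FrequencyDomainSettings) -> float:
    """Lifetime (ns) from the measured phase shift: tau = tan(phase)/omega."""
    if not (0.0 <= phase < 0.5 * math.pi):
        raise OutOfRangeError("phase must lie in [0, pi/2)")
    return math.tan(phase) / settings.omega


def phase_mixture_discrepancy(
    params: LifetimeParams, phi_F: float, settings: FrequencyDomainSettings
) -> float:
    """Signed error (ns) of the phase-estimated mixture lifetime relative to
    the fraction-weighted average tau_mix.

    Quantifies the domain of validity of the weighted-average assumption:
    the discrepancy vanishes as E -> 0 or as the modulation frequency -> 0.
    """
    target = mixture_lifetime(params, phi_F).tau_mix
    phase = simulate_phase(
        [params.tau_D, params.tau_f], [1.0 - phi_F, phi_F], settings
    )
    return phase_lifetime(phase, settings) - target


def fit_linearity(series: MeasurementSeries) -> LinearFit:
    """Ordinary least-squares line through a titration series.

    For lifetime series the fitted line tau_mix = intercept + slope*phi_F
    identifies the donor lifetime (intercept) and the per-molecule efficiency
    E = -slope/intercept.
    """
    fr, obs = series.fractions, series.observables
    if fr.size < 3:
        raise DegenerateSeriesError("need at least 3 points to assess linearity")
    if np.unique(fr).size < 2:
        raise DegenerateSeriesError("need at least 2 distinct fractions")
    res = stats.linregress(fr, obs)
    r2 = float(res.rvalue**2)
    e_est = None
    if series.observable == "tau":
        if res.intercept == 0:
            raise DegenerateSeriesError("zero intercept: cannot form -slope/intercept")
        e_est = float(-res.slope / res.intercept)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        E_estimate=e_est,
    )
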