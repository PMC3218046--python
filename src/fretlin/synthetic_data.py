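"""Synthetic mixture experiments for exercising every estimator end-to-end.

Three plate designs mirror the canonical in-vitro validation experiments for
linear FRET quantification:

``gtp_gdp``
    A two-state GTPase (Raichu-type) probe: every molecule is a tandem
    construct, a fraction phi is locked in the high-FRET (GTP) state and the
    rest in the low-FRET (GDP) state.  Per-state apparent FRETing fractions
    are calibrated at construction so the noise-free conventional ratio runs
    from 1.80 (all GDP) to 2.10 (all GTP) — a span small enough that the
    inherently curved R response looks effectively straight.

``tandem_vs_donor``
    Dilution series of donor-only protein against a fixed-efficiency
    donor-acceptor tandem fusion at constant total donor; the workhorse for
    lifetime titrations and for exposing the curvature of R over a wide
    ratio range.

``constant_acceptor``
    Like ``tandem_vs_donor`` but free acceptor is added as the tandem is
    diluted so the *total* acceptor (monomer plus tandem) stays constant
    across the series — the design under which the directly excited acceptor
    intensity is a constant normalizer and R_alt is affine in the tandem
    fraction.

Generators emit either observable series or full plate-scan tables (one well
per fraction; a 436 nm excitation scan over 480-565 nm and a 505 nm
excitation scan over 525-565 nm, both on the 5 nm grid).  Noise is
multiplicative Gaussian on each individual scan intensity (plate-reader
shot/gain noise is proportional and acts per reading) and additive Gaussian
on lifetimes.  All randomness flows from the design's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import flim
from .errors import DesignError, InvalidParameterError
from .spectra import (
    ACCEPTOR_BAND,
    DONOR_BAND,
    FRET_BAND,
    GRID_STEP,
    Band,
    CoverageFractions,
    EmissionSpectrum,
    band_photon_sum,
    channel_sum,
    synth_emission_spectrum,
)

__all__ = [
    "DONOR_EXCITATION_NM",
    "ACCEPTOR_EXCITATION_NM",
    "GTP_GDP_R_ENDPOINTS",
    "NoiseModel",
    "MixtureDesign",
    "default_donor_spectrum",
    "default_acceptor_spectrum",
    "design_coverage",
    "gtp_gdp_state_fractions",
    "generate_series",
    "generate_scan_plate",
]

DONOR_EXCITATION_NM = 436.0
ACCEPTOR_EXCITATION_NM = 505.0
_DONOR_SCAN = np.arange(480.0, 565.0 + 0.5, GRID_STEP)   # 18 wavelengths
_ACCEPTOR_SCAN = np.arange(525.0, 565.0 + 0.5, GRID_STEP)  # 9 wavelengths

# noise-free conventional-ratio endpoints the gtp_gdp design is calibrated to
GTP_GDP_R_ENDPOINTS = (1.80, 2.10)

_KINDS = ("gtp_gdp", "tandem_vs_donor", "constant_acceptor")


def default_donor_spectrum() -> EmissionSpectrum:
    """Synthetic mTFP1-like donor: log-normal lineshape, mode 492 nm, QY 0.85."""
    return synth_emission_spectrum(peak=492.0, width=14.0, skew=0.35, quantum_yield=0.85)


def default_acceptor_spectrum() -> EmissionSpectrum:
    """Synthetic mVenus-like acceptor: log-normal lineshape, mode 528 nm, QY 0.57."""
    return synth_emission_spectrum(peak=528.0, width=16.0, skew=0.35, quantum_yield=0.57)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: relative sd per scan intensity reading, additive sd
    (ns) per lifetime reading."""

    intensity_cv: float = 0.01
    lifetime_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.intensity_cv < 0 or self.lifetime_sd < 0:
            raise InvalidParameterError("noise parameters must be non-negative")


@dataclass(frozen=True)
class MixtureDesign:
    """A mixture titration: which experiment, at which fractions, how noisy."""

    kind: str
    n_points: int = 11
    fractions: np.ndarray | None = None
    E: float = 0.25
    tau_D: float = 2.94
    donor: EmissionSpectrum = field(default_factory=default_donor_spectrum)
    acceptor: EmissionSpectrum = field(default_factory=default_acceptor_spectrum)
    total_probe: float = 1e4
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise DesignError(f"unknown design kind {self.kind!r}; expected one of {_KINDS}")
        if self.fractions is None:
            if self.n_points < 2:
                raise DesignError("need at least 2 fractions")
            fr = np.linspace(0.0, 1.0, self.n_points)
        else:
            fr = np.asarray(self.fractions, dtype=float)
            if fr.size < 2 or np.any(np.diff(fr) < 0):
                raise DesignError("fractions must be sorted, length >= 2")
            if fr.min() < 0 or fr.max() > 1:
                raise DesignError("fractions must lie in [0, 1]")
            object.__setattr__(self, "n_points", int(fr.size))
        object.__setattr__(self, "fractions", fr)
        if not (0.0 <= self.E < 1.0):
            raise InvalidParameterError("E must lie in [0, 1)")
        if self.tau_D <= 0:
            raise InvalidParameterError("tau_D must be positive")
        if self.total_probe <= 0:
            raise DesignError(
                "total_probe must be positive (a constant_acceptor design with "
                "no acceptor is inconsistent)"
            )

    def with_(self, **kw) -> "MixtureDesign":
        return replace(self, **kw)


def design_coverage(design: MixtureDesign, fret_band: Band = FRET_BAND) -> CoverageFractions:
    """Discrete-grid capture coefficients of the design's spectra.

    f_AD is taken over the band the conventional ratio uses: the nominal FRET
    channel for gtp_gdp (as in the Raichu experiment), the acceptor channel
    otherwise.
    """
    band = fret_band if design.kind == "gtp_gdp" else ACCEPTOR_BAND
    return CoverageFractions(
        f_DD=band_photon_sum(design.donor, DONOR_BAND),
        f_AD=band_photon_sum(design.donor, band),
        f_AA=band_photon_sum(design.acceptor, band),
        f_DA=band_photon_sum(design.acceptor, DONOR_BAND),
    )


def gtp_gdp_state_fractions(
    design: MixtureDesign,
    r_endpoints: tuple[float, float] = GTP_GDP_R_ENDPOINTS,
) -> tuple[float, float]:
    """Apparent FRETing fractions (E*phi per molecule) of the GDP and GTP
    states, calibrated so the noise-free ratio endpoints match ``r_endpoints``.

    Inverts R = [x f_AA + (1-x) f_AD] / [(1-x) f_DD + x f_DA] for x at each
    endpoint (the small acceptor leak f_DA into the donor band is kept so the
    calibration matches the simulated plate exactly).
    """
    cov = design_coverage(design)
    xs = []
    for R in r_endpoints:
        num = R * cov.f_DD - cov.f_AD
        den = num + cov.f_AA - R * cov.f_DA
        if den <= 0:
            raise DesignError("ratio endpoint unreachable: acceptor leak dominates")
        xs.append(num / den)
    x_lo, x_hi = xs
    if not (0.0 <= x_lo < x_hi < 1.0):
        raise DesignError(
            f"calibrated state fractions ({x_lo:.3f}, {x_hi:.3f}) leave [0, 1): "
            "ratio endpoints unreachable with these spectra"
        )
    return float(x_lo), float(x_hi)


def _composition(design: MixtureDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-well (apparent FRETing fraction, donor count, acceptor count)."""
    fr = design.fractions
    n = design.total_probe
    if design.kind == "tandem_vs_donor":
        x_bar = design.E * fr
        n_donor = np.full_like(fr, n)
        n_acceptor = fr * n
    elif design.kind == "constant_acceptor":
        x_bar = design.E * fr
        n_donor = np.full_like(fr, n)
        n_acceptor = np.full_like(fr, n)  # tandem + free monomer
    else:  # gtp_gdp
        x_lo, x_hi = gtp_gdp_state_fractions(design)
        x_bar = (1.0 - fr) * x_lo + fr * x_hi
        n_donor = np.full_like(fr, n)
        n_acceptor = np.full_like(fr, n)
    return x_bar, n_donor, n_acceptor


def _well_label(i: int) -> str:
    row, col = divmod(i, 12)
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def generate_scan_plate(design: MixtureDesign, seed: int | None = None) -> pd.DataFrame:
    """Simulate the plate-reader scan table for a design.

    One well per fraction; per well a 436 nm-excitation emission scan over
    480-565 nm (donor + FRET channels) and a 505 nm-excitation scan over
    525-565 nm (direct acceptor), both at 5 nm steps.  Columns:
    ``well, excitation_nm, emission_nm, intensity``.
    """
    if design.n_points > 96:
        raise DesignError("more fractions than wells in a 96-well plate")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    x_bar, n_donor, n_acceptor = _composition(design)

    d_dens = np.interp(_DONOR_SCAN, design.donor.wavelengths, design.donor.density,
                       left=0.0, right=0.0) * design.donor.quantum_yield * GRID_STEP
    a_dens = np.interp(_DONOR_SCAN, design.acceptor.wavelengths, design.acceptor.density,
                       left=0.0, right=0.0) * design.acceptor.quantum_yield * GRID_STEP
    a_dens_acc = np.interp(_ACCEPTOR_SCAN, design.acceptor.wavelengths,
                           design.acceptor.density, left=0.0, right=0.0) \
        * design.acceptor.quantum_yield * GRID_STEP

    rows: list[tuple[str, float, float, float]] = []
    for i in range(design.n_points):
        well = _well_label(i)
        # donor excitation: quenched donor emission plus FRET-sensitized acceptor
        don_scan = n_donor[i] * (1.0 - x_bar[i]) * d_dens + n_donor[i] * x_bar[i] * a_dens
        acc_scan = n_acceptor[i] * a_dens_acc
        for lam, inten in zip(_DONOR_SCAN, don_scan):
            rows.append((well, DONOR_EXCITATION_NM, float(lam), float(inten)))
        for lam, inten in zip(_ACCEPTOR_SCAN, acc_scan):
            rows.append((well, ACCEPTOR_EXCITATION_NM, float(lam), float(inten)))

    table = pd.DataFrame(rows, columns=["well", "excitation_nm", "emission_nm", "intensity"])
    if design.noise.intensity_cv > 0:
        factors = 1.0 + design.noise.intensity_cv * rng.standard_normal(len(table))
        table["intensity"] = np.clip(table["intensity"].to_numpy() * factors, 0.0, None)
    return table


def series_from_plate(
    plate: pd.DataFrame, design: MixtureDesign, observable: str
) -> flim.MeasurementSeries:
    """Reduce a scan table to a (fraction, ratio) series via channel sums."""
    if observable not in ("R", "R_alt"):
        raise DesignError(f"plate reduction supports R/R_alt, not {observable!r}")
    num_band = FRET_BAND if design.kind == "gtp_gdp" else ACCEPTOR_BAND
    values = []
    for i in range(design.n_points):
        w = plate[plate["well"] == _well_label(i)]
        don_exc = w[w["excitation_nm"] == DONOR_EXCITATION_NM]
        acc_exc = w[w["excitation_nm"] == ACCEPTOR_EXCITATION_NM]
        i_d = channel_sum(don_exc, DONOR_BAND)
        if observable == "R":
            values.append(channel_sum(don_exc, num_band) / i_d)
        else:
            values.append(i_d / channel_sum(acc_exc, ACCEPTOR_BAND))
    return flim.MeasurementSeries(
        fractions=design.fractions,
        observables=np.asarray(values),
        noise_sd=design.noise.intensity_cv,
        observable=observable,
    )


def generate_series(
    design: MixtureDesign, observable: str = "tau", seed: int | None = None
) -> flim.MeasurementSeries:
    """Generate a (fraction, observable) titration series.

    ``observable``: "tau" (mixture lifetime, ns, additive noise), "R"
    (conventional ratio) or "R_alt" (donor over direct-acceptor ratio);
    ratio observables are computed by channel sums over a simulated plate so
    they agree with :func:`generate_scan_plate` exactly in the noise-free
    limit.
    """
    if observable == "tau":
        rng = np.random.default_rng(design.seed if seed is None else seed)
        x_bar, _, _ = _composition(design)
        tau = design.tau_D * (1.0 - x_bar)
        if design.noise.lifetime_sd > 0:
            tau = tau + design.noise.lifetime_sd * rng.standard_normal(tau.shape)
        return flim.MeasurementSeries(
            fractions=design.fractions,
            observables=tau,
            noise_sd=design.noise.lifetime_sd,
            observable="tau",
        )
    plate = generate_scan_plate(design, seed=seed)
    return series_from_plate(plate, design, observable)
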