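"""Emission spectra, channel bands and capture coefficients.

A plate reader quantifies a FRET construct through *channels*: sums of
emission intensities over closed wavelength bands on a 5 nm scan grid.  The
standard channel definitions are

* donor channel    480-500 nm,
* acceptor channel 525-565 nm,
* nominal FRET channel 515-565 nm,

and the link between a fluorophore's emission spectrum and a channel is its
*capture coefficient*: quantum yield times the fraction of the (unit
normalized) emission density falling inside the band, in photons per
molecule.  f_DD is donor emission captured by the donor channel, f_AD donor
emission bleeding into the acceptor channel (crosstalk), f_AA acceptor
emission captured by the acceptor channel.

mTFP1/mVenus emission spectra are not tabulated here; `synth_emission_spectrum`
builds synthetic log-normal stand-ins (only ratios of band integrals enter the
ratio models, so the precise lineshape is immaterial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InvalidParameterError, MalformedTableError

__all__ = [
    "GRID_STEP",
    "DONOR_BAND",
    "ACCEPTOR_BAND",
    "FRET_BAND",
    "Band",
    "EmissionSpectrum",
    "CoverageFractions",
    "coverage_fraction",
    "band_photon_sum",
    "coverage_set",
    "synth_emission_spectrum",
    "channel_sum",
    "overlap_index_series",
]

GRID_STEP = 5.0  # nm, the native plate-scan sampling interval


@dataclass(frozen=True)
class Band:
    """Closed emission wavelength interval [lo, hi] in nm."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise InvalidParameterError(f"band lo {self.lo} > hi {self.hi}")


DONOR_BAND = Band(480.0, 500.0)
ACCEPTOR_BAND = Band(525.0, 565.0)
FRET_BAND = Band(515.0, 565.0)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Normalized emission density on a strictly increasing wavelength grid.

    ``density`` integrates (trapezoid rule) to 1 over the grid;
    ``quantum_yield`` converts the unit integral into photons per excited
    molecule.
    """

    wavelengths: np.ndarray
    density: np.ndarray
    quantum_yield: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "density", dens)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise InvalidParameterError("wavelength grid must be 1-D, strictly increasing")
        if dens.shape != wl.shape:
            raise InvalidParameterError("density and wavelengths must have matching shape")
        if np.any(dens < 0):
            raise InvalidParameterError("emission density must be non-negative")
        if not (0.0 < self.quantum_yield <= 1.0):
            raise InvalidParameterError("quantum yield must lie in (0, 1]")
        total = float(np.trapezoid(dens, wl))
        if abs(total - 1.0) > 1e-6:
            raise InvalidParameterError(
                f"density must integrate to 1 (got {total:.8f}); use .normalized()"
            )

    @classmethod
    def normalized(
        cls, wavelengths: Sequence[float], density: Sequence[float],
        quantum_yield: float = 1.0,
    ) -> "EmissionSpectrum":
        wl = np.asarray(wavelengths, dtype=float)
        dens = np.asarray(density, dtype=float)
        total = np.trapezoid(dens, wl)
        if total <= 0:
            raise InvalidParameterError("cannot normalize an all-zero density")
        return cls(wl, dens / total, quantum_yield)

    @classmethod
    def from_csv(cls, path, quantum_yield: float = 1.0) -> "EmissionSpectrum":
        """Read a `wavelength_nm,density` table and renormalize."""
        df = pd.read_csv(path)
        missing = {"wavelength_nm", "density"} - set(df.columns)
        if missing:
            raise MalformedTableError(f"spectrum CSV missing columns: {sorted(missing)}")
        df = df.sort_values("wavelength_nm")
        return cls.normalized(df["wavelength_nm"], df["density"], quantum_yield)


@dataclass(frozen=True)
class CoverageFractions:
    """Emission-capture coefficients linking spectra to channel intensities.

    f_DD : donor emission captured by the donor channel (photons/molecule)
    f_AD : donor emission captured by the acceptor channel (crosstalk)
    f_AA : acceptor emission captured by the acceptor channel
    f_DA : acceptor emission captured by the donor channel; 0 by default
           since acceptor emission is easily excluded from the donor channel
    """

    f_DD: float
    f_AD: float
    f_AA: float
    f_DA: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_DD", "f_AD", "f_AA", "f_DA"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")


def coverage_fraction(spectrum: EmissionSpectrum, band: Band) -> float:
    """Photons per molecule captured in ``band``: quantum yield times the
    trapezoid integral of the emission density over the band.

    Partial overlap with the stored grid is handled by interpolating the
    density at the clipped band edges; zero-width and non-overlapping bands
    return 0.
    """
    wl, dens = spectrum.wavelengths, spectrum.density
    lo = max(band.lo, float(wl[0]))
    hi = min(band.hi, float(wl[-1]))
    if lo >= hi:
        return 0.0
    inner = wl[(wl > lo) & (wl < hi)]
    xs = np.concatenate(([lo], inner, [hi]))
    ys = np.interp(xs, wl, dens)
    return float(spectrum.quantum_yield * np.trapezoid(ys, xs))


def band_photon_sum(spectrum: EmissionSpectrum, band: Band, step: float = GRID_STEP) -> float:
    """Discrete-grid analogue of :func:`coverage_fraction`.

    Resamples the density at the plate reader's ``step`` nm grid points inside
    the closed band and returns ``quantum_yield * step * sum`` — exactly the
    quantity a channel sum over a scan of this fluorophore measures, up to the
    per-molecule excitation count.  Used by the synthetic plate generator so
    channel sums and model ratios agree to machine precision.
    """
    if band.lo % step or band.hi % step:
        raise GridMismatchError(
            f"band [{band.lo}, {band.hi}] endpoints must sit on the {step:g} nm grid"
        )
    pts = np.arange(band.lo, band.hi + 0.5 * step, step)
    ys = np.interp(pts, spectrum.wavelengths, spectrum.density, left=0.0, right=0.0)
    return float(spectrum.quantum_yield * step * np.sum(ys))


def coverage_set(
    donor: EmissionSpectrum,
    acceptor: EmissionSpectrum,
    donor_band: Band = DONOR_BAND,
    acceptor_band: Band = ACCEPTOR_BAND,
    discrete: bool = False,
) -> CoverageFractions:
    """Build the (f_DD, f_AD, f_AA) coefficient set for a donor/acceptor pair.

    With ``discrete=True`` the coefficients use the 5 nm grid sums (matching
    plate channel sums) instead of trapezoid integrals.
    """
    cov = band_photon_sum if discrete else coverage_fraction
    return CoverageFractions(
        f_DD=cov(donor, donor_band),
        f_AD=cov(donor, acceptor_band),
        f_AA=cov(acceptor, acceptor_band),
    )


def synth_emission_spectrum(
    peak: float,
    width: float,
    skew: float = 0.0,
    quantum_yield: float = 1.0,
    grid: np.ndarray | None = None,
) -> EmissionSpectrum:
    """Synthetic fluorescent-protein emission spectrum (log-normal lineshape).

    ``peak`` places the mode (nm), ``width`` sets the spread (nm, roughly the
    standard deviation), and ``skew`` controls the red tail typical of FP
    emission; ``skew = 0`` degenerates to a symmetric Gaussian.  The density
    is renormalized to unit integral on the returned grid.
    """
    if width <= 0:
        raise InvalidParameterError("width must be positive")
    if skew < 0:
        raise InvalidParameterError("skew must be non-negative")
    if grid is None:
        grid = np.arange(400.0, 700.0 + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)

    if skew == 0.0:
        dens = np.exp(-0.5 * ((grid - peak) / width) ** 2)
    else:
        s = skew
        scale = width / s
        loc = peak - scale * np.exp(-s * s)  # mode at `peak` exactly
        x = grid - loc
        dens = np.zeros_like(grid)
        pos = x > 0
        dens[pos] = np.exp(-0.5 * (np.log(x[pos] / scale) / s) ** 2) / x[pos]
    return EmissionSpectrum.normalized(grid, dens, quantum_yield)


def channel_sum(scan: pd.DataFrame, band: Band) -> float:
    """Channel intensity: sum of scan intensities at 5 nm grid wavelengths
    lambda with ``band.lo <= lambda <= band.hi`` (both endpoints included).

    ``scan`` must carry `emission_nm` and `intensity` columns (one well and
    one excitation's worth of rows).
    """
    missing = {"emission_nm", "intensity"} - set(scan.columns)
    if missing:
        raise MalformedTableError(f"scan table missing columns: {sorted(missing)}")
    if band.lo % GRID_STEP or band.hi % GRID_STEP:
        raise GridMismatchError(
            f"band [{band.lo}, {band.hi}] endpoints must sit on the {GRID_STEP:g} nm grid"
        )
    wl = scan["emission_nm"].to_numpy(dtype=float)
    mask = (wl >= band.lo) & (wl <= band.hi)
    return float(scan.loc[mask, "intensity"].sum())


def overlap_index_series(
    donor: EmissionSpectrum,
    acceptor: EmissionSpectrum | None = None,
) -> list[tuple[Band, float]]:
    """Crosstalk proxy for each of the nested FRET-channel band variants.

    The FRET channel upper edge stays at 565 nm while the lower edge steps
    from 535 nm down to 480 nm in 5 nm decrements (12 bands).  For each band
    the proxy is donor coverage of that band over donor coverage of the donor
    channel — proportional to f_AD/f_DD, the overlap index.  The series is
    non-decreasing as the bands widen.
    """
    ref = coverage_fraction(donor, DONOR_BAND)
    if ref <= 0:
        raise InvalidParameterError("donor spectrum has no weight in the donor channel")
    out = []
    for lo in np.arange(535.0, 479.0, -GRID_STEP):
        band = Band(float(lo), 565.0)
        out.append((band, coverage_fraction(donor, band) / ref))
    return out
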