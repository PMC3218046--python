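# Methods

## Scope and model structure

`fretlin` treats a unimolecular FRET probe as a two-state molecule: a
fraction φ_F of probes sits in the FRET-competent conformation, and each
competent probe transfers energy with per-molecule efficiency E. Every
observable in the package is a deterministic function of (E, φ_F) plus
instrument parameters; estimators invert those functions. The package's
central claim, carried by the forward models and verified by the tests, is
that τ_mix and R_alt are affine in φ_F while the conventional ratio R and
R_alt⁻¹ are not, so only the former support linear calibration of the
active-probe fraction.

## Probe-activation cycle

The activation cycle is the covalent-modification (Goldbeter–Koshland)
scheme: a forward enzyme converts P to P\* with maximal activity F_a and
Michaelis constant K_MF, a reverse enzyme reverts it (R_a, K_MR), and
P + P\* = P_TOT. Activities are Vmax-type rates (concentration·time⁻¹);
this is a reconstruction — with first-order "activities" the saturated
balances would not be dimensionally consistent. Steady states:

* forward saturated / reverse linear: F_a = R_a·P\*/K_MR ⇒
  P\* = F_a·K_MR/R_a — the only regime in which P\* is proportional to F_a;
* forward linear / reverse saturated: P\* = P_TOT − R_a·K_MF/F_a;
* both linear: P\* = P_TOT·(F_a/K_MF)/((F_a/K_MF) + (R_a/K_MR));
* full Michaelis–Menten: the unique root in [0, P_TOT] of a quadratic.
  Roots are computed with the numerically stable ±-pairing; if rounding
  puts two roots inside the interval the one with the smaller rate
  imbalance wins (uniqueness is analytic, ties are float noise).

A closed form that leaves [0, P_TOT] raises a regime-inconsistency error
instead of being clipped: it means the assumed operating limit cannot hold.
Two independent oracles validate the algebra: Brent root-bracketing of the
rate balance, and LSODA time integration from P\*(0) = 0 in geometrically
doubling chunks (near a zero-order-ultrasensitive steady state the final
relaxation rate scales like F_a·K_MF/P_TOT² and can be orders of magnitude
slower than the naive P_TOT/rate time scale). `linearity_deviation` reports
the maximum residual of P\*(F_a) from its least-squares line, normalized by
the response range. Default relative tolerance is 1e-8 throughout,
configurable per call.

## Spectra and channels

Channels are closed wavelength bands on the 5 nm plate-scan grid: donor
480–500 nm, acceptor 525–565 nm, nominal FRET channel 515–565 nm; channel
sums include both endpoints. Capture coefficients f_XY = quantum yield ×
band integral of the unit-normalized emission density (photons per
molecule). Two integration dialects coexist deliberately: trapezoid
integrals with edge interpolation (`coverage_fraction`, exact band
additivity, used for continuous spectra) and 5 nm grid sums
(`band_photon_sum`, exactly what a plate channel sum measures, used by the
synthetic plate generator so that channel sums and closed-form ratios agree
to machine precision). Detector spectral response is folded into per-channel
gain multipliers in the ratiometric module, not into the f coefficients.

mTFP1- and mVenus-like fixtures are *synthetic* log-normal lineshapes
(modes 492 and 528 nm, widths 14 and 16 nm, skew 0.35, quantum yields 0.85
and 0.57 — literature-typical values). Only ratios of band integrals enter
any estimator, so the precise lineshape is immaterial; the log-normal
parameterization places the mode exactly at the nominal peak and
degenerates to a Gaussian at zero skew. The overlap-index series mirrors the
band-variation protocol (FRET-channel lower edge stepped 535 → 480 nm, 12
bands) and reports donor coverage of each band relative to donor-channel
coverage; any positive rescaling of this proxy is equally valid since the
index is only defined up to proportionality to f_AD/f_DD.

## Ratiometric model

Channel components (gains g_D, g_A):

    I_DD = g_D·N_D*·(1 − Eφ_F)·f_DD      I_AD = g_A·N_D*·(1 − Eφ_F)·f_AD
    I_AA = g_A·(N_D*·Eφ_F + N_A^direct)·f_AA
    I_DA = g_D·(N_D*·Eφ_F + N_A^direct)·f_DA   (f_DA defaults to 0)

R = I_A^don/I_D^don carries (1 − Eφ_F) in its denominator and is therefore
convex and strictly increasing in φ_F; its zero-FRET baseline is
f_AD/f_DD. R_alt = I_D^don/I_A^acc normalizes by the directly excited
acceptor intensity — FRET-independent by the assumption that acceptor
excitation does not excite the donor — and is exactly affine in φ_F with
negative slope. `r_surface` evaluates R over an (Eφ_F, f_AD/f_DD) grid (the
Eφ_F axis capped below 1; the standard plotted range is 0–0.6 with
f_AA/f_DD ≈ 1). `naive_fraction_from_R` applies endpoint linear
interpolation to R so the resulting bias (e.g. −0.21 at E = 0.6,
φ_F = 0.5 with matched coverages and no crosstalk) is computable rather
than hidden; the bias vanishes as E → 0, which is why narrow-range probes
look deceptively linear.

## Lifetimes and frequency-domain phase

E = 1 − τ_f/τ links efficiency to donor lifetimes without/with acceptor;
rate-constant and lifetime parameterizations (k_f = 1/τ, E = k_et/(k_f +
k_et)) are interconvertible and tested mutually consistent. The mixture
model τ_mix = τ·(1 − E·φ_F) assumes the measured lifetime is the
molecule-fraction-weighted average of the two populations. OLS over a
titration then gives E = −slope/intercept; reported efficiencies round to
the nearest percent.

The phase simulator audits that assumption. Each mono-exponential component
contributes the demodulation response 1/(1 + iωτ), components are weighted
by *emitted-photon* fraction (molecular fraction × lifetime, since
steady-state brightness scales with lifetime), and the phase lifetime is
tan(arctan(S/G))/ω. Default modulation frequency is 40 MHz, a typical
choice for nanosecond lifetimes; the fluorescein reference (4.0 ns) closes
the mono-exponential round trip to 1e-9 ns. Two biases separate the phase
estimate from τ_mix: the non-linearity of the complex sum (grows with ω and
E) and brightness weighting, which survives ω → 0 — the low-frequency limit
is the intensity-weighted mean Σfτ²/Σfτ, 0.05 ns above the
molecule-weighted average for a 50/50 donor/tandem mixture. This is exactly
the "method biases the estimate toward one population" caveat on the
weighted-average model, quantified.

## Calibration

φ_a = (F_mix − F_in)/(F_act − F_in) for any observable affine in the active
fraction; affine-invariant and orientation-independent. F_mix may overshoot
the calibration interval by a configurable clamp band (default 2% of the
interval, absorbing endpoint noise in the saturating-inhibitor references)
and is clamped into [0, 1]; larger overshoots raise an error. Readings of
the conventional ratio R are refused unless the caller opts into the biased
naive interpolation explicitly — there is no unbiased linear inversion
for R.

## Synthetic designs and noise

All three designs put one well per mixing fraction (default 11 equally
spaced fractions), with two exposures per well: a 436 nm-excitation
emission scan over 480–565 nm and a 505 nm-excitation scan over 525–565 nm,
both on the 5 nm grid.

* `tandem_vs_donor`: total donor constant; a fraction φ of molecules is
  tandem with E = 0.25, τ_D = 2.94 ns, tandem τ_f = 2.205 ns (the package's
  canonical donor/tandem fixture).
* `constant_acceptor`: as above, but free acceptor replaces the diluted
  tandem so total acceptor is constant — the direct-acceptor channel is
  then constant up to noise and R_alt is affine in φ.
* `gtp_gdp`: every molecule is a two-state tandem; per-state apparent
  FRETing fractions are solved at construction so the noise-free
  conventional ratio (nominal FRET channel over donor channel) runs exactly
  from 1.80 to 2.10. The inversion accounts for the small acceptor leak
  f_DA into the donor band present in the simulated scans. Over this narrow
  span the convex R(φ) deviates from its endpoint chord by ≈ 2.8% of the
  span (0.0085 ratio units) — the analytic sag is
  0.075·f_DD/(R̄·f_DD − f_AD + f_AA) of the span and cannot drop below
  ~2% for any donor/acceptor pair with quantum yields ≤ 1 — which is far
  below realistic measurement scatter and is why a narrow-range probe
  appears linear even though R is not.

Noise: multiplicative Gaussian with CV 1% applied independently to each
(well, excitation, emission) intensity reading — plate-reader shot/gain
noise is proportional and acts per reading, so channel sums inherit a
smaller effective CV through averaging — and additive Gaussian with sd
0.02 ns on lifetimes (consistent with a ±0.07 ns 95% CI on a pure-donor
measurement). Intensities are clipped at zero. All draws come from
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
tables through the deterministic CSV writer. Free acceptor contributes
nothing under donor excitation (no direct excitation, no intermolecular
FRET), matching the experimental null at the dilute concentrations these
titrations emulate.

What the generators do *not* emulate: photobleaching, detector
nonlinearity and saturation, monochromator bandwidth, pixel-level FLIM
statistics, autofluorescence backgrounds, and intermolecular FRET at high
concentration. Passing tests therefore demonstrate correctness of the
estimators under the stated measurement model, not robustness to every
artifact of real plates.

## Problem sizes

Tests and the acceptance script use 11–21-fraction series, 100–200 seeded
replicates for stochastic statistics (median R², unbiasedness,
parameter-recovery means) and 100 random parameter draws for the
steady-state oracle cross-checks; the full suite runs in a few seconds.

## Known limitations

* Mono-exponential donors only; multi-exponential donors (e.g. ECFP) are
  out of scope, as is modulation-depth lifetime estimation.
* The steady-state module is exactly that — transients are touched only by
  the ODE oracle, and intracellular systems far from steady state need an
  explicit kinetic model.
* The Eφ_F parameterization is exposed directly; E and φ_F are not
  separately identifiable from a single ratiometric or lifetime
  measurement without a titration or calibration endpoints.
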