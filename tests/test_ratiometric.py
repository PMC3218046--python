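"""Channel forward model, the ratio estimators R and R_alt, and the
linearity/non-linearity dichotomy between them."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fretlin import ratiometric as rm
from fretlin.errors import CalibrationError, OutOfRangeError
from fretlin.spectra import CoverageFractions


def affine_residual(x, y):
    """Max |residual| of the least-squares line through (x, y)."""
    coef = np.polyfit(x, y, 1)
    return float(np.max(np.abs(y - np.polyval(coef, x))))


class TestChannelIntensities:
    def test_no_fret_baseline(self, simple_cov, unit_excitation):
        ch = rm.channel_intensities(rm.FretState(E=0.3, phi_F=0.0), unit_excitation, simple_cov)
        assert ch.I_D_don == pytest.approx(1000 * 0.4)
        assert ch.I_A_don == pytest.approx(1000 * 0.1)  # crosstalk only

    def test_complete_transfer(self, simple_cov):
        exc = rm.ExcitationState(N_D_star=1000.0, N_A_direct=50.0)
        ch = rm.channel_intensities(rm.FretState(E=1.0, phi_F=1.0), exc, simple_cov)
        assert ch.I_D_don == 0.0
        assert ch.I_A_don == pytest.approx((1000 + 50) * 0.35)

    def test_hand_worked_intensities(self, simple_cov, unit_excitation):
        # N_D*=1000, E=0.3, phi_F=0.5 -> E*phi_F = 0.15
        ch = rm.channel_intensities(rm.FretState(E=0.3, phi_F=0.5), unit_excitation, simple_cov)
        assert ch.I_D_don == pytest.approx(340.0)    # 1000*0.85*0.4
        assert ch.I_A_don == pytest.approx(137.5)    # 1000*(0.15*0.35 + 0.85*0.1)


class TestRatioR:
    def test_crosstalk_only_baseline(self, simple_cov, unit_excitation):
        R = rm.ratio_R(rm.FretState(E=0.5, phi_F=0.0), unit_excitation, simple_cov)
        assert R == pytest.approx(0.1 / 0.4)

    def test_hand_worked_ratio(self, simple_cov, unit_excitation):
        R = rm.ratio_R(rm.FretState(E=0.3, phi_F=0.5), unit_excitation, simple_cov)
        assert R == pytest.approx(137.5 / 340.0)

    def test_no_crosstalk_matched_coverages(self, unit_excitation):
        cov = CoverageFractions(f_DD=0.4, f_AD=0.0, f_AA=0.4)
        R = rm.ratio_R(rm.FretState(E=0.6, phi_F=1.0), unit_excitation, cov)
        assert R == pytest.approx(0.6 / 0.4)  # = 1.5 at E*phi_F = 0.6

    def test_undefined_at_complete_transfer(self, simple_cov, unit_excitation):
        with pytest.raises(OutOfRangeError):
            rm.ratio_R(rm.FretState(E=1.0, phi_F=1.0), unit_excitation, simple_cov)

    def test_closed_form_consistency(self, simple_cov, unit_excitation):
        """R from channel intensities equals the algebraic form."""
        for e, phi in [(0.25, 0.3), (0.6, 0.9), (0.05, 1.0)]:
            x = e * phi
            closed = (x * simple_cov.f_AA + (1 - x) * simple_cov.f_AD) / ((1 - x) * simple_cov.f_DD)
            got = rm.ratio_R(rm.FretState(E=e, phi_F=phi), unit_excitation, simple_cov)
            assert got == pytest.approx(closed, rel=1e-12)


class TestRatioRalt:
    def test_no_fret_baseline(self, simple_cov, unit_excitation):
        R_alt = rm.ratio_R_alt(rm.FretState(E=0.3, phi_F=0.0), unit_excitation, simple_cov)
        assert R_alt == pytest.approx(1000 * 0.4 / (1000 * 0.35))

    def test_hand_worked_value(self, simple_cov, unit_excitation):
        R_alt = rm.ratio_R_alt(rm.FretState(E=0.3, phi_F=0.5), unit_excitation, simple_cov)
        assert R_alt == pytest.approx(0.85 * 0.4 / 0.35)

    def test_midpoint_exactness(self, simple_cov, unit_excitation):
        vals = [
            rm.ratio_R_alt(rm.FretState(E=0.3, phi_F=p), unit_excitation, simple_cov)
            for p in (0.0, 0.5, 1.0)
        ]
        assert vals[1] == pytest.approx((vals[0] + vals[2]) / 2, abs=1e-12)

    def test_undefined_without_direct_acceptor_signal(self, simple_cov):
        exc = rm.ExcitationState(N_D_star=1000.0, N_A_acc=0.0)
        with pytest.raises(OutOfRangeError):
            rm.ratio_R_alt(rm.FretState(E=0.3, phi_F=0.5), exc, simple_cov)


class TestLinearityDichotomy:
    """R_alt is exactly affine in phi_F; R and 1/R_alt are not."""

    @given(
        e=st.floats(0.05, 0.95),
        f_dd=st.floats(0.1, 1.0),
        f_ad=st.floats(0.0, 0.5),
        f_aa=st.floats(0.1, 1.0),
        n_d=st.floats(10.0, 1e6),
        n_a=st.floats(10.0, 1e6),
    )
    @settings(max_examples=50, deadline=None)
    def test_r_alt_affine_r_curved(self, e, f_dd, f_ad, f_aa, n_d, n_a):
        cov = CoverageFractions(f_DD=f_dd, f_AD=f_ad, f_AA=f_aa)
        exc = rm.ExcitationState(N_D_star=n_d, N_A_acc=n_a)
        phis = np.linspace(0, 1, 11)
        r_alt = np.array([rm.ratio_R_alt(rm.FretState(e, p), exc, cov) for p in phis])
        r = np.array([rm.ratio_R(rm.FretState(e, p), exc, cov) for p in phis])
        span_alt = np.ptp(r_alt)
        assert affine_residual(phis, r_alt) < 1e-10 * max(span_alt, 1.0)
        assert affine_residual(phis, r) > 1e-8 * np.ptp(r)
        assert affine_residual(phis, 1.0 / r_alt) > 1e-8 * np.ptp(1.0 / r_alt)

    def test_monotone_in_phi(self, simple_cov, unit_excitation):
        phis = np.linspace(0, 1, 21)
        r = [rm.ratio_R(rm.FretState(0.4, p), unit_excitation, simple_cov) for p in phis]
        r_alt = [rm.ratio_R_alt(rm.FretState(0.4, p), unit_excitation, simple_cov) for p in phis]
        assert np.all(np.diff(r) > 0)
        assert np.all(np.diff(r_alt) < 0)

    def test_gain_invariance(self, simple_cov):
        state = rm.FretState(E=0.3, phi_F=0.4)
        base = rm.ExcitationState(1000.0, 0.0, 1000.0, gain_D=1.0, gain_A=1.0)
        both = rm.ExcitationState(1000.0, 0.0, 1000.0, gain_D=3.0, gain_A=3.0)
        acc_only = rm.ExcitationState(1000.0, 0.0, 1000.0, gain_D=1.0, gain_A=2.0)
        # common gain cancels in both ratios
        assert rm.ratio_R(state, both, simple_cov) == pytest.approx(
            rm.ratio_R(state, base, simple_cov), rel=1e-12
        )
        assert rm.ratio_R_alt(state, both, simple_cov) == pytest.approx(
            rm.ratio_R_alt(state, base, simple_cov), rel=1e-12
        )
        # acceptor-channel gain scales R, and 1/R_alt, proportionally
        assert rm.ratio_R(state, acc_only, simple_cov) == pytest.approx(
            2 * rm.ratio_R(state, base, simple_cov), rel=1e-12
        )
        assert 1 / rm.ratio_R_alt(state, acc_only, simple_cov) == pytest.approx(
            2 / rm.ratio_R_alt(state, base, simple_cov), rel=1e-12
        )


class TestRSurface:
    def test_zero_fret_column_is_the_crosstalk_grid(self):
        ct = np.linspace(0.0, 1.0, 11)
        surf = rm.r_surface(np.array([0.0]), ct)
        np.testing.assert_allclose(surf[0], ct)

    def test_corner_value(self):
        surf = rm.r_surface(np.array([0.0, 0.6]), np.array([0.0]), f_AA_over_f_DD=1.0)
        assert surf[1, 0] == pytest.approx(1.5)

    def test_monotone_and_convex_along_fret_axis(self):
        e_phi = np.linspace(0.0, 0.6, 25)
        ct = np.linspace(0.0, 1.0, 11)
        surf = rm.r_surface(e_phi, ct)
        d1 = np.diff(surf, axis=0)
        d2 = np.diff(surf, n=2, axis=0)
        assert np.all(d1 > 0)
        assert np.all(d2 > 0)
        assert np.all(np.diff(surf[1:], axis=1) > 0)  # increasing in crosstalk too

    def test_grid_reaching_one_rejected(self):
        with pytest.raises(OutOfRangeError):
            rm.r_surface(np.array([0.0, 1.0]), np.array([0.0]))


class TestNaiveFractionFromR:
    def test_bias_at_high_efficiency(self, unit_excitation):
        cov = CoverageFractions(f_DD=0.4, f_AD=0.0, f_AA=0.4)
        r = {
            p: rm.ratio_R(rm.FretState(E=0.6, phi_F=p), unit_excitation, cov)
            for p in (0.0, 0.5, 1.0)
        }
        naive = rm.naive_fraction_from_R(r[0.5], r[1.0], r[0.0])
        assert naive == pytest.approx((0.3 / 0.7) / 1.5, rel=1e-9)  # ~0.2857
        assert naive - 0.5 == pytest.approx(-0.214, abs=0.001)

    def test_endpoint(self):
        assert rm.naive_fraction_from_R(1.2, 2.0, 1.2) == 0.0

    def test_degenerate_calibration(self):
        with pytest.raises(CalibrationError):
            rm.naive_fraction_from_R(1.0, 1.5, 1.5)

    def test_bias_vanishes_as_efficiency_shrinks(self, unit_excitation):
        cov = CoverageFractions(f_DD=0.4, f_AD=0.0, f_AA=0.4)
        biases = []
        for e in (0.3, 0.03, 0.003):
            r = {
                p: rm.ratio_R(rm.FretState(E=e, phi_F=p), unit_excitation, cov)
                for p in (0.0, 0.5, 1.0)
            }
            biases.append(abs(rm.naive_fraction_from_R(r[0.5], r[1.0], r[0.0]) - 0.5))
        assert biases[0] > biases[1] > biases[2]
        assert biases[2] < 1e-3
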