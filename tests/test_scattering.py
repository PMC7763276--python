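"""Closed-form scattering laws against independent oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from osmoqens.constants import HBAR_MEV_PS
from osmoqens.scattering import (
    CompositeSpectrumModel,
    ConfinedRotationParams,
    DebyeWallerFactor,
    JumpDiffusionParams,
    LorentzianComponent,
    brownian_hwhm,
    convolve_resolution,
    eisf_with_immobile,
    evaluate_composite,
    impulse_density,
    jump_diffusion_hwhm,
    lorentzian_density,
    rotational_hwhm,
    sphere_eisf,
)


def j1_reference(x):
    """First-order spherical Bessel function, written out independently."""
    return np.sin(x) / x**2 - np.cos(x) / x


class TestLorentzian:
    def test_peak_value(self):
        assert lorentzian_density(0.0, 0.1) == pytest.approx(1.0 / (0.1 * np.pi))

    def test_half_maximum_at_hwhm(self):
        g = 0.37
        assert lorentzian_density(g, g) == pytest.approx(0.5 * lorentzian_density(0.0, g))

    def test_integral_matches_arctan_closed_form(self):
        # finite-window integral has the closed form (2/pi) arctan(W/Γ)
        g = 0.2
        omega = np.linspace(-50 * g, 50 * g, 200001)
        num = np.trapezoid(lorentzian_density(omega, g), omega)
        assert num == pytest.approx(2.0 / np.pi * np.arctan(50.0), abs=1e-6)

    @given(st.floats(0.01, 5.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_normalization_closed_form_any_width(self, g):
        omega = np.linspace(-500 * g, 500 * g, 100001)
        num = np.trapezoid(lorentzian_density(omega, g), omega)
        assert num == pytest.approx(2.0 / np.pi * np.arctan(500.0), abs=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            lorentzian_density(0.0, 0.0)


class TestJumpDiffusion:
    def test_zero_q(self):
        assert jump_diffusion_hwhm(JumpDiffusionParams(0.117, 3.3), 0.0) == 0.0

    def test_reference_value(self):
        # D_T = 1.17e-5 cm²/s = 0.117 Å²/ps, τ₀ = 3.3 ps, Q = 1 Å⁻¹
        got = jump_diffusion_hwhm(JumpDiffusionParams(0.117, 3.3), 1.0)
        expected = HBAR_MEV_PS * 0.117 / (1.0 + 0.117 * 3.3)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.0556, abs=2e-4)

    def test_asymptote_hbar_over_tau(self):
        jd = JumpDiffusionParams(0.117, 3.3)
        assert jump_diffusion_hwhm(jd, 1e5) == pytest.approx(HBAR_MEV_PS / 3.3, rel=1e-4)

    @given(st.floats(0.01, 1.0), st.floats(0.1, 20.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, d_t, tau0):
        jd = JumpDiffusionParams(d_t, tau0)
        q = np.linspace(0.0, 10.0, 200)
        g = jump_diffusion_hwhm(jd, q)
        assert np.all(np.diff(g) > 0)
        assert np.all(g <= HBAR_MEV_PS / tau0 + 1e-12)

    def test_brownian_reference_and_equivalence(self):
        assert brownian_hwhm(0.117, 1.0) == pytest.approx(0.0770, abs=2e-4)
        q = np.linspace(0.0, 3.0, 20)
        np.testing.assert_allclose(
            brownian_hwhm(0.117, q),
            jump_diffusion_hwhm(JumpDiffusionParams(0.117, 0.0), q),
        )

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            JumpDiffusionParams(-1.0, 0.0)
        with pytest.raises(ValueError):
            JumpDiffusionParams(0.1, -1.0)


class TestSphereEisf:
    def test_q_zero_limit(self):
        assert sphere_eisf(2.0, 0.0) == pytest.approx(1.0)

    def test_against_bessel_oracle(self):
        # QR = 1 evaluated through the explicit sin/cos expression
        expected = (3.0 * j1_reference(1.0)) ** 2
        assert sphere_eisf(2.0, 0.5) == pytest.approx(expected)
        assert sphere_eisf(2.0, 0.5) == pytest.approx(0.8164, abs=1e-4)

    def test_first_zero_location(self):
        # the EISF vanishes where j1 does; root found on the oracle
        x0 = brentq(j1_reference, 3.0, 6.0)
        assert x0 == pytest.approx(4.4934, abs=1e-4)
        assert sphere_eisf(1.0, x0) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(0.1, 10.0), st.floats(0.0, 20.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_unit_interval(self, r, q):
        val = sphere_eisf(r, q)
        assert 0.0 <= val <= 1.0 + 1e-12

    def test_monotone_decreasing_to_first_zero(self):
        x = np.linspace(0.0, 4.4934, 400)
        vals = sphere_eisf(1.0, x)
        assert np.all(np.diff(vals) < 1e-12)


class TestEisfWithImmobile:
    def test_fully_immobile(self):
        params = ConfinedRotationParams(p=1.0, R=2.0)
        assert eisf_with_immobile(params, 7.3) == pytest.approx(1.0)

    def test_reduces_to_sphere(self):
        params = ConfinedRotationParams(p=0.0, R=2.0)
        q = np.linspace(0, 4, 30)
        np.testing.assert_allclose(eisf_with_immobile(params, q), sphere_eisf(2.0, q))

    def test_mixture_value(self):
        params = ConfinedRotationParams(p=0.5, R=2.0)
        expected = 0.5 + 0.5 * (3.0 * j1_reference(1.0)) ** 2
        assert eisf_with_immobile(params, 0.5) == pytest.approx(expected)
        assert eisf_with_immobile(params, 0.5) == pytest.approx(0.9082, abs=1e-4)

    @given(st.floats(0.0, 1.0), st.floats(0.5, 5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_large_q_limit(self, p, r):
        params = ConfinedRotationParams(p=p, R=r)
        q = np.linspace(0.0, 30.0 / r, 300)
        vals = np.atleast_1d(eisf_with_immobile(params, q))
        assert np.all(vals >= p - 1e-12)
        assert np.all(vals <= 1.0 + 1e-12)
        # far beyond the first oscillations the curve settles onto p
        assert eisf_with_immobile(params, 500.0 / r) == pytest.approx(p, abs=1e-4)


class TestRotationalWidth:
    @pytest.mark.parametrize(
        "d_r,l,expected",
        [(0.24, 1, 0.48), (0.0, 3, 0.0), (0.1, 2, 0.6)],
    )
    def test_multipole_widths(self, d_r, l, expected):
        params = ConfinedRotationParams(p=0.5, R=2.0, D_R=d_r)
        assert rotational_hwhm(params, l) == pytest.approx(expected)

    def test_invalid_multipole(self):
        with pytest.raises(ValueError):
            rotational_hwhm(ConfinedRotationParams(p=0.5, R=2.0, D_R=0.1), 0)


class TestCompositeSpectrum:
    def _grid(self):
        return np.linspace(-5.0, 5.0, 1001)

    def test_pure_elastic(self):
        omega = self._grid()
        shape = impulse_density(omega)
        model = CompositeSpectrumModel(
            dw=DebyeWallerFactor(0.0), elastic_amplitude=2.5, q=1.0
        )
        np.testing.assert_allclose(evaluate_composite(model, omega, shape), 2.5 * shape)

    def test_debye_waller_damping(self):
        omega = self._grid()
        shape = impulse_density(omega)
        lor = (LorentzianComponent(hwhm=0.3, amplitude=1.0),)
        undamped = CompositeSpectrumModel(DebyeWallerFactor(0.0), 1.0, lor, q=1.5)
        damped = CompositeSpectrumModel(DebyeWallerFactor(0.6), 1.0, lor, q=1.5)
        ratio = evaluate_composite(damped, omega, shape) / evaluate_composite(
            undamped, omega, shape
        )
        np.testing.assert_allclose(ratio, np.exp(-0.6 * 1.5**2 / 3.0))

    def test_grid_integral_oracle(self):
        # trapezoid integral must equal DW·(A0+ΣAi) + background integral
        omega = self._grid()
        shape = impulse_density(omega)
        model = CompositeSpectrumModel(
            dw=DebyeWallerFactor(0.4),
            elastic_amplitude=1.2,
            lorentzians=(
                LorentzianComponent(0.05, 0.6),
                LorentzianComponent(0.4, 0.3),
            ),
            bg_intercept=0.01,
            bg_slope=0.001,
            q=1.0,
        )
        vals = evaluate_composite(model, omega, shape)
        dw = np.exp(-0.4 / 3.0)
        # Lorentzian tails escape the finite window; integrate what remains
        lor_in_window = sum(
            a * 2.0 / np.pi * np.arctan(5.0 / g) for g, a in [(0.05, 0.6), (0.4, 0.3)]
        )
        expected = dw * (1.2 + lor_in_window) + 0.01 * 10.0
        assert np.trapezoid(vals, omega) == pytest.approx(expected, rel=2e-3)

    def test_reduces_to_brownian_law(self):
        omega = self._grid()
        g = HBAR_MEV_PS * 0.117
        model = CompositeSpectrumModel(
            dw=DebyeWallerFactor(0.0),
            elastic_amplitude=0.0,
            lorentzians=(LorentzianComponent(g, 1.0),),
            q=1.0,
        )
        vals = evaluate_composite(model, omega, impulse_density(omega))
        np.testing.assert_allclose(vals, lorentzian_density(omega, g))

    def test_nonuniform_grid_rejected(self):
        omega = np.array([0.0, 0.1, 0.3])
        model = CompositeSpectrumModel(DebyeWallerFactor(0.0), 1.0)
        with pytest.raises(ValueError):
            evaluate_composite(model, omega, np.ones(3))


class TestConvolution:
    def _grid(self, step=0.01, half=5.0):
        n = int(round(2 * half / step)) + 1
        return -half + step * np.arange(n), step

    def test_impulse_identity(self):
        omega, step = self._grid()
        signal = np.exp(-(omega**2))
        out = convolve_resolution(signal, impulse_density(omega), step)
        np.testing.assert_allclose(out, signal, atol=1e-12)

    def test_lorentzian_closure(self):
        omega, step = self._grid(0.005, 20.0)
        g1, g2 = 0.1, 0.25
        out = convolve_resolution(
            lorentzian_density(omega, g1), lorentzian_density(omega, g2), step
        )
        expected = lorentzian_density(omega, g1 + g2)
        core = np.abs(omega) < 5.0
        np.testing.assert_allclose(out[core], expected[core], rtol=2e-2)

    def test_gaussian_closure(self):
        omega, step = self._grid(0.005, 5.0)
        s1, s2 = 0.1, 0.15
        g = lambda s: np.exp(-0.5 * (omega / s) ** 2) / (s * np.sqrt(2 * np.pi))
        out = convolve_resolution(g(s1), g(s2), step)
        np.testing.assert_allclose(out, g(np.hypot(s1, s2)), atol=1e-6)

    def test_commutative_and_linear(self):
        omega, step = self._grid()
        a = lorentzian_density(omega, 0.2)
        b = np.exp(-0.5 * (omega / 0.1) ** 2)
        ab = convolve_resolution(a, b, step)
        ba = convolve_resolution(b, a, step)
        np.testing.assert_allclose(ab, ba, atol=1e-10)
        two = convolve_resolution(2.0 * a, b, step)
        np.testing.assert_allclose(two, 2.0 * ab, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            convolve_resolution(np.ones(10), np.ones(11), 0.1)
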