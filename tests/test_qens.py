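"""QENS reduction and model fitting: corrections, round trips, EISF, transport."""

from dataclasses import replace

import numpy as np
import pytest

from osmoqens.constants import HBAR_MEV_PS
from osmoqens.qens import (
    EisfCurve,
    QENSSpectra,
    SampleFit,
    compute_eisf,
    fit_buffer,
    fit_eisf,
    fit_jump_diffusion_widths,
    fit_sample,
    fit_transport,
    interpolate_buffer,
    normalize_vanadium,
    subtract_background_spectra,
)
from osmoqens.scattering import (
    ConfinedRotationParams,
    JumpDiffusionParams,
    eisf_with_immobile,
    jump_diffusion_hwhm,
)
from osmoqens.synthetic import REFERENCE_CONDITIONS, gen_qens_dataset


def small_spectra(role="sample", nq=3, nw=21, value=1.0, conc=0.0):
    omega = np.linspace(-1.0, 1.0, nw)
    counts = np.full((nq, nw), value)
    return QENSSpectra(
        role=role,
        q_list=np.linspace(0.5, 1.5, nq),
        omega_grid=omega,
        counts=counts,
        errors=np.sqrt(counts),
        concentration=conc,
    )


class TestCorrections:
    def test_subtract_identity(self):
        s = small_spectra(value=5.0)
        zero = small_spectra(role="empty", value=0.0)
        out = subtract_background_spectra(s, zero, None, 0.0)
        np.testing.assert_array_equal(out.counts, s.counts)

    def test_subtract_exact_cancellation(self):
        empty = small_spectra(role="empty", value=2.0)
        buf = small_spectra(role="buffer", value=3.0)
        s = small_spectra(value=5.0)
        out = subtract_background_spectra(s, empty, buf, 1.0)
        np.testing.assert_array_equal(out.counts, np.zeros_like(s.counts))

    def test_error_propagation_quadrature(self):
        s = small_spectra(value=4.0)
        empty = small_spectra(role="empty", value=1.0)
        buf = small_spectra(role="buffer", value=1.0)
        out = subtract_background_spectra(s, empty, buf, 0.5)
        expected = np.sqrt(4.0 + 1.0 + 0.25 * 1.0)
        np.testing.assert_allclose(out.errors, expected)

    def test_negative_bins_clipped(self):
        s = small_spectra(value=1.0)
        empty = small_spectra(role="empty", value=2.0)
        out = subtract_background_spectra(s, empty, None, 0.0)
        assert np.all(out.counts == 0.0)

    def test_grid_mismatch_rejected(self):
        s = small_spectra(nw=21)
        other = small_spectra(role="empty", nw=31)
        with pytest.raises(ValueError):
            subtract_background_spectra(s, other, None, 0.0)

    @pytest.mark.parametrize("wt,w0", [(0.0, 1.0), (15.0, 0.0), (5.0, 2.0 / 3.0)])
    def test_buffer_interpolation_weights(self, wt, w0):
        b0 = small_spectra(role="buffer", value=1.0)
        b15 = small_spectra(role="buffer", value=4.0)
        out = interpolate_buffer(b0, b15, wt)
        np.testing.assert_allclose(out.counts, w0 * 1.0 + (1 - w0) * 4.0)

    def test_buffer_interpolation_range(self):
        b = small_spectra(role="buffer")
        with pytest.raises(ValueError):
            interpolate_buffer(b, b, 20.0)

    def test_vanadium_uniform_rescaling(self):
        s = small_spectra(value=6.0)
        van = small_spectra(role="vanadium", value=3.0)
        out, res = normalize_vanadium(s, van)
        np.testing.assert_allclose(out.counts, 6.0 / (3.0 * 2.0))
        np.testing.assert_allclose(np.trapezoid(res, s.omega_grid, axis=1), 1.0)

    def test_vanadium_doubling_halves_one_q(self):
        s = small_spectra(value=6.0)
        van = small_spectra(role="vanadium", value=3.0)
        van.counts[1] *= 2.0
        out, _ = normalize_vanadium(s, van)
        assert out.counts[1, 0] == pytest.approx(out.counts[0, 0] / 2.0)

    def test_resolution_width_matches_generator(self, in6):
        # second moment of the returned lineshape vs the generator Gaussian
        data = gen_qens_dataset(replace(REFERENCE_CONDITIONS[0.0], peak_counts=None), in6)
        _, res = normalize_vanadium(data["sample"], data["vanadium"])
        omega = in6.omega_grid
        sigma_est = np.sqrt(np.trapezoid(omega**2 * res[0], omega))
        sigma_true = 2.0 * in6.resolution_hwhm / 2.3548200450309493
        assert sigma_est == pytest.approx(sigma_true, rel=1e-3)

    def test_zero_vanadium_rejected(self):
        s = small_spectra()
        van = small_spectra(role="vanadium", value=0.0)
        with pytest.raises(ValueError):
            normalize_vanadium(s, van)


@pytest.fixture(scope="module")
def clean_dataset(in6):
    truth = replace(REFERENCE_CONDITIONS[0.0], peak_counts=None)
    return truth, gen_qens_dataset(truth, in6)


@pytest.fixture(scope="module")
def clean_buffer_model(clean_dataset, in6):
    _, data = clean_dataset
    buffer_n, _ = normalize_vanadium(data["buffer"], data["vanadium"])
    _, resolution = normalize_vanadium(data["sample"], data["vanadium"])
    return fit_buffer(buffer_n, resolution, seed=0), resolution


class TestBufferFit:
    def test_noise_free_round_trip(self, clean_dataset, clean_buffer_model):
        truth, _ = clean_dataset
        bm, _ = clean_buffer_model
        assert bm.jd.D_T == pytest.approx(truth.buffer_jd.D_T, rel=0.01)
        assert bm.jd.tau0 == pytest.approx(truth.buffer_jd.tau0, rel=0.01)
        assert bm.rot_width == pytest.approx(truth.buffer_rot_width, rel=0.01)
        assert bm.amplitude_ratio == pytest.approx(truth.buffer_ratio, rel=0.01)

    def test_poisson_replicates_recover_d_t(self, in6):
        # counting noise at 1e4 peak counts; the replicate mean must land
        # within 5% of the generating diffusion coefficient
        estimates = []
        for rep in range(10):
            truth = replace(REFERENCE_CONDITIONS[0.0], seed=700 + rep)
            data = gen_qens_dataset(truth, in6)
            bn, res = normalize_vanadium(data["buffer"], data["vanadium"])
            bm = fit_buffer(bn, res, seed=rep)
            estimates.append(bm.jd.D_T)
        assert np.mean(estimates) == pytest.approx(0.117, rel=0.05)

    def test_too_few_q_rejected(self):
        b = small_spectra(role="buffer", nq=3)
        with pytest.raises(ValueError):
            fit_buffer(b, np.ones((3, 21)), seed=0)


class TestSampleFit:
    def test_noise_free_exact_recovery(self, clean_dataset, clean_buffer_model, in6):
        truth, data = clean_dataset
        bm, resolution = clean_buffer_model
        sn, _ = normalize_vanadium(data["sample"], data["vanadium"])
        sf = fit_sample(sn, bm, resolution, seed=1)
        np.testing.assert_allclose(
            sf.narrow_hwhm, jump_diffusion_hwhm(truth.sample_jd, sf.q_list), rtol=1e-4
        )
        np.testing.assert_allclose(sf.broad_hwhm, 2 * truth.sample_rot.D_R, rtol=1e-4)
        assert np.nanmax(sf.chi2) < 1e-6

    def test_buffer_free_data_matches_direct_fit(self, in6):
        # on data with no solvent signal, fitting with the frozen buffer
        # component free must agree with the plain four-component fit to
        # within the fits' own width uncertainties
        truth = replace(REFERENCE_CONDITIONS[0.0], buffer_in_sample=0.0, seed=55)
        data = gen_qens_dataset(truth, in6)
        sn, resolution = normalize_vanadium(data["sample"], data["vanadium"])
        bn, _ = normalize_vanadium(data["buffer"], data["vanadium"])
        direct = fit_sample(sn, None, resolution, seed=2)
        bm = fit_buffer(bn, resolution, seed=0)
        with_buffer = fit_sample(sn, bm, resolution, seed=2)
        diff = np.abs(direct.narrow_hwhm - with_buffer.narrow_hwhm)
        sig = np.sqrt(
            np.nan_to_num(direct.narrow_hwhm_err) ** 2
            + np.nan_to_num(with_buffer.narrow_hwhm_err) ** 2
        )
        assert np.all(diff <= np.maximum(sig, 1e-3))


class TestEisf:
    def _manual_fit(self, a0, an, ab):
        nq = len(a0)
        z = np.zeros(nq)
        return SampleFit(
            q_list=np.linspace(0.4, 2.0, nq),
            buffer_scale=z,
            elastic_amplitude=np.asarray(a0, float),
            elastic_amplitude_err=0.01 * np.asarray(a0, float),
            narrow_hwhm=np.full(nq, 0.05),
            narrow_hwhm_err=z + 0.001,
            narrow_amplitude=np.asarray(an, float),
            narrow_amplitude_err=0.01 * np.asarray(an, float) + 1e-6,
            broad_hwhm=np.full(nq, 0.5),
            broad_hwhm_err=z + 0.001,
            broad_amplitude=np.asarray(ab, float),
            broad_amplitude_err=0.01 * np.asarray(ab, float) + 1e-6,
            bg_slope=z,
            bg_intercept=z,
            chi2=np.ones(nq),
            flags=[[] for _ in range(nq)],
            covar=[None] * nq,
        )

    def test_pure_elastic_gives_unity(self):
        fit = self._manual_fit([1.0] * 6, [0.0] * 6, [0.0] * 6)
        curve = compute_eisf(fit)
        np.testing.assert_allclose(curve.a0, 1.0)

    def test_equal_split_gives_half(self):
        fit = self._manual_fit([1.0] * 6, [0.6] * 6, [0.4] * 6)
        curve = compute_eisf(fit)
        np.testing.assert_allclose(curve.a0, 0.5)

    def test_scale_invariance(self):
        fit1 = self._manual_fit([1.0] * 6, [0.3] * 6, [0.2] * 6)
        fit2 = self._manual_fit([3.0] * 6, [0.9] * 6, [0.6] * 6)
        np.testing.assert_allclose(compute_eisf(fit1).a0, compute_eisf(fit2).a0)

    def test_round_trip_through_pipeline(self, clean_dataset, clean_buffer_model, in6):
        # the generating law p + (1-p)[3j₁(QR)/QR]² must come back exactly
        truth, data = clean_dataset
        bm, resolution = clean_buffer_model
        sn, _ = normalize_vanadium(data["sample"], data["vanadium"])
        sf = fit_sample(sn, bm, resolution, seed=1)
        curve = compute_eisf(sf)
        expected = eisf_with_immobile(truth.sample_rot, curve.q)
        np.testing.assert_allclose(curve.a0, expected, atol=1e-4)

    def test_fit_eisf_exact(self):
        q = np.linspace(0.3, 2.5, 12)
        a0 = eisf_with_immobile(ConfinedRotationParams(p=0.5, R=2.0), q)
        p, _, r, _, flags = fit_eisf(EisfCurve(q=q, a0=a0, a0_error=np.full(12, 0.01)))
        assert p == pytest.approx(0.5, abs=1e-6)
        assert r == pytest.approx(2.0, abs=1e-5)
        assert not flags

    def test_fit_eisf_degenerate_flat_curve_flagged(self):
        q = np.linspace(0.3, 2.5, 10)
        a0 = np.ones(10)
        p, _, r, _, flags = fit_eisf(EisfCurve(q=q, a0=a0, a0_error=np.full(10, 0.01)))
        assert p >= 0.99
        assert "R_unidentifiable" in flags


class TestTransport:
    def test_exact_widths_recovered(self):
        q = np.linspace(0.4, 2.0, 12)
        jd = JumpDiffusionParams(0.29, 5.5)
        widths = jump_diffusion_hwhm(jd, q)
        got, _, _ = fit_jump_diffusion_widths(q, widths, np.full(12, 1e-4))
        assert got.D_T == pytest.approx(0.29, rel=1e-5)
        assert got.tau0 == pytest.approx(5.5, rel=1e-5)

    def test_constant_broad_width_halved(self):
        nq = 8
        q = np.linspace(0.4, 2.0, nq)
        jd = JumpDiffusionParams(0.29, 5.5)
        fit = SampleFit(
            q_list=q,
            buffer_scale=np.zeros(nq),
            elastic_amplitude=np.ones(nq),
            elastic_amplitude_err=np.full(nq, 0.01),
            narrow_hwhm=np.asarray(jump_diffusion_hwhm(jd, q)),
            narrow_hwhm_err=np.full(nq, 1e-4),
            narrow_amplitude=np.ones(nq),
            narrow_amplitude_err=np.full(nq, 0.01),
            broad_hwhm=np.full(nq, 0.48),
            broad_hwhm_err=np.full(nq, 0.01),
            broad_amplitude=np.ones(nq),
            broad_amplitude_err=np.full(nq, 0.01),
            bg_slope=np.zeros(nq),
            bg_intercept=np.zeros(nq),
            chi2=np.ones(nq),
            flags=[[] for _ in range(nq)],
            covar=[None] * nq,
        )
        tp = fit_transport(fit)
        assert tp.D_R == pytest.approx(0.24, rel=1e-6)
        assert tp.D_T == pytest.approx(2.9, rel=1e-4)  # 1e-5 cm²/s scale
        assert tp.tau0 == pytest.approx(5.5, rel=1e-4)

    def test_dip_window_exclusion_harmless_without_dip(self):
        # synthetic widths carry no coherent dip, so masking the window
        # must not move the fit beyond its own uncertainty
        rng = np.random.default_rng(8)
        q = np.linspace(0.4, 2.2, 14)
        jd = JumpDiffusionParams(0.117, 3.3)
        widths = jump_diffusion_hwhm(jd, q) * (1 + 0.03 * rng.standard_normal(q.size))
        errs = 0.03 * np.asarray(jump_diffusion_hwhm(jd, q))
        with_dip, (d_err, _), _ = fit_jump_diffusion_widths(
            q, widths, errs, exclude_q2_window=(2.0, 3.0)
        )
        without, _, _ = fit_jump_diffusion_widths(q, widths, errs, exclude_q2_window=None)
        assert abs(with_dip.D_T - without.D_T) < max(d_err, 0.01)


class TestEndToEnd:
    def test_full_noise_free_chain(self, clean_dataset, in6):
        from osmoqens.pipeline import analyze_condition

        truth, data = clean_dataset
        res = analyze_condition(
            data["sample"], data["buffer"], data["empty"], data["vanadium"], seed=3
        )
        tp = res["transport"]
        assert tp.D_T == pytest.approx(10 * truth.sample_jd.D_T, rel=1e-3)
        assert tp.tau0 == pytest.approx(truth.sample_jd.tau0, rel=1e-3)
        assert tp.D_R == pytest.approx(truth.sample_rot.D_R, rel=1e-3)
        assert tp.p == pytest.approx(truth.sample_rot.p, abs=1e-3)
        assert tp.R == pytest.approx(truth.sample_rot.R, rel=1e-3)
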