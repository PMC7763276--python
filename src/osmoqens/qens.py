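"""Quasi-elastic spectrum reduction and model fitting.

The workflow mirrors standard practice on time-of-flight/backscattering
spectrometers:

1. subtract empty-cell and (fractionally) buffer spectra from the sample;
2. normalize to a vanadium measurement, which supplies the per-detector
   efficiency and the instrumental resolution lineshape S_res(Q, ω);
3. fit the buffer alone with two resolution-convolved Lorentzians
   (translational jump diffusion + Q-independent rotation);
4. fit the sample with the buffer pair frozen (widths and internal ratio
   fixed, one free scale), an elastic line shaped like the resolution, two
   free sample Lorentzians and a linear background;
5. extract the EISF A₀(Q) = elastic / (elastic + quasi-elastic) and fit the
   sphere-confinement model with immobile fraction;
6. fit the narrow sample widths with the jump-diffusion law and the broad
   widths with a constant to obtain D_T, τ₀ and D_R = Γ_broad/2.

Weighted nonlinear least squares throughout (lmfit), with multi-start
jittering to avoid local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import HBAR_MEV_PS, d_to_reported_scale
from .scattering import (
    JumpDiffusionParams,
    _check_uniform,
    convolve_resolution,
    eisf_with_immobile,
    jump_diffusion_hwhm,
    lorentzian_density,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QENSSpectra",
    "BufferModel",
    "SampleFit",
    "EisfCurve",
    "TransportParams",
    "subtract_background_spectra",
    "interpolate_buffer",
    "normalize_vanadium",
    "fit_buffer",
    "fit_sample",
    "compute_eisf",
    "fit_eisf",
    "fit_jump_diffusion_widths",
    "fit_transport",
]

#: default Q² window (Å⁻²) excluded from buffer jump-diffusion fits,
#: bracketing the coherent de Gennes narrowing dip of D₂O
DEFAULT_DIP_WINDOW: tuple[float, float] = (2.0, 3.0)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class QENSSpectra:
    """Per-Q energy spectra with uncertainties for one measurement role."""

    role: str
    q_list: np.ndarray
    omega_grid: np.ndarray
    counts: np.ndarray
    errors: np.ndarray
    concentration: float = 0.0
    temperature: float = 310.0
    #: monitor (counting-time) factor: counts are proportional to it, so
    #: spectra divided by their monitors share one absolute intensity scale
    monitor: float = 1.0

    _ROLES = frozenset({"sample", "buffer", "empty", "vanadium"})

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {sorted(self._ROLES)}, got {self.role!r}")
        self.q_list = np.asarray(self.q_list, dtype=float)
        self.omega_grid = np.asarray(self.omega_grid, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.omega_step = _check_uniform(self.omega_grid)
        expected = (self.q_list.size, self.omega_grid.size)
        if self.counts.shape != expected or self.errors.shape != expected:
            raise ValueError(f"counts/errors must have shape {expected}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def _like(self, counts: np.ndarray, errors: np.ndarray, role: str | None = None) -> "QENSSpectra":
        return QENSSpectra(
            role=role or self.role,
            q_list=self.q_list.copy(),
            omega_grid=self.omega_grid.copy(),
            counts=counts,
            errors=errors,
            concentration=self.concentration,
            temperature=self.temperature,
            monitor=self.monitor,
        )


def _check_same_grid(a: QENSSpectra, b: QENSSpectra) -> None:
    if a.q_list.shape != b.q_list.shape or not np.allclose(a.q_list, b.q_list):
        raise ValueError(f"Q grids differ between {a.role} and {b.role}")
    if a.omega_grid.shape != b.omega_grid.shape or not np.allclose(a.omega_grid, b.omega_grid):
        raise ValueError(f"omega grids differ between {a.role} and {b.role}")


@dataclass
class BufferModel:
    """Two-Lorentzian description of the solvent, with a global jump-diffusion law."""

    q_list: np.ndarray
    narrow_hwhm: np.ndarray
    narrow_hwhm_err: np.ndarray
    broad_hwhm: np.ndarray
    amplitude_ratio: float  # broad / narrow intensity, fixed in sample fits
    jd: JumpDiffusionParams
    jd_err: tuple[float, float]  # (D_T, tau0) standard errors, Å²/ps and ps
    rot_width: float  # Q-averaged broad width, meV
    rot_width_err: float
    fitted_q_mask: np.ndarray = field(default=None)  # Qs that entered the global fit
    # per-Q fitted intensities and the buffer measurement's monitor, so the
    # solvent component can be carried into sample fits on the shared
    # absolute scale where its coefficient is a physical volume fraction
    narrow_amp: np.ndarray = field(default=None)
    broad_amp: np.ndarray = field(default=None)
    monitor: float = 1.0


@dataclass
class SampleFit:
    """Per-Q constrained fit results for a protein sample."""

    q_list: np.ndarray
    buffer_scale: np.ndarray
    elastic_amplitude: np.ndarray
    elastic_amplitude_err: np.ndarray
    narrow_hwhm: np.ndarray
    narrow_hwhm_err: np.ndarray
    narrow_amplitude: np.ndarray
    narrow_amplitude_err: np.ndarray
    broad_hwhm: np.ndarray
    broad_hwhm_err: np.ndarray
    broad_amplitude: np.ndarray
    broad_amplitude_err: np.ndarray
    bg_slope: np.ndarray
    bg_intercept: np.ndarray
    chi2: np.ndarray  # reduced chi-square per Q
    flags: list  # per-Q list of strings; empty list = clean fit
    covar: list = field(default=None)  # per-Q covariance of (A0, A_nar, A_brd)
    # joint-fit width parameters (D_T Å²/ps, τ₀ ps, Γ_broad meV) with
    # standard errors, when the globally constrained protocol ran
    global_widths: dict = field(default=None)


@dataclass
class EisfCurve:
    """Elastic incoherent structure factor A₀(Q) with propagated errors."""

    q: np.ndarray
    a0: np.ndarray
    a0_error: np.ndarray


@dataclass
class TransportParams:
    """Headline dynamical parameters with standard errors.

    D_T is reported on the conventional 1e-5 cm²/s scale, τ₀ in ps, the
    rotational constant D_R in meV, the immobile fraction p dimensionless
    and the confinement radius R in Å.
    """

    D_T: float
    D_T_err: float
    tau0: float
    tau0_err: float
    D_R: float = float("nan")
    D_R_err: float = float("nan")
    p: float = float("nan")
    p_err: float = float("nan")
    R: float = float("nan")
    R_err: float = float("nan")


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------

def subtract_background_spectra(
    sample: QENSSpectra,
    empty: QENSSpectra | None,
    buffer: QENSSpectra | None,
    buffer_fraction: float = 1.0,
) -> QENSSpectra:
    """Subtract empty-cell and a fraction of the buffer from the sample.

    Errors propagate in quadrature; bins driven negative are clipped to zero
    (their number is logged).
    """
    counts = sample.counts.copy()
    var = sample.errors**2
    if empty is not None:
        _check_same_grid(sample, empty)
        counts = counts - empty.counts
        var = var + empty.errors**2
    if buffer is not None and buffer_fraction != 0.0:
        _check_same_grid(sample, buffer)
        counts = counts - buffer_fraction * buffer.counts
        var = var + (buffer_fraction * buffer.errors) ** 2
    n_neg = int(np.count_nonzero(counts < 0))
    if n_neg:
        logger.info("subtract_background_spectra: clipped %d negative bins to zero", n_neg)
        counts = np.clip(counts, 0.0, None)
    return sample._like(counts, np.sqrt(var))


def interpolate_buffer(buf0: QENSSpectra, buf15: QENSSpectra, wt: float) -> QENSSpectra:
    """Linear bin-by-bin interpolation of buffer spectra between 0 and 15 wt%."""
    if not 0.0 <= wt <= 15.0:
        raise ValueError(f"wt must lie in [0, 15], got {wt}")
    _check_same_grid(buf0, buf15)
    t = wt / 15.0
    counts = (1.0 - t) * buf0.counts + t * buf15.counts
    errors = np.sqrt(((1.0 - t) * buf0.errors) ** 2 + (t * buf15.errors) ** 2)
    out = buf0._like(counts, errors)
    out.concentration = wt
    out.monitor = (1.0 - t) * buf0.monitor + t * buf15.monitor
    return out


def normalize_vanadium(
    spectra: QENSSpectra, vanadium: QENSSpectra
) -> tuple[QENSSpectra, np.ndarray]:
    """Normalize spectra to the vanadium integral; return the resolution lineshapes.

    Vanadium scatters almost purely incoherently and elastically, so its
    integral measures the relative detector efficiency at each Q and its
    lineshape is the instrumental resolution S_res(Q, ω), returned here
    unit-normalized (one row per Q).
    """
    if spectra.q_list.size != vanadium.q_list.size or not np.allclose(
        spectra.q_list, vanadium.q_list
    ):
        raise ValueError("spectra and vanadium must share the Q list")
    integrals = np.trapezoid(vanadium.counts, vanadium.omega_grid, axis=1)
    if np.any(integrals <= 0):
        raise ValueError("vanadium integral is zero at some Q")
    counts = spectra.counts / integrals[:, None]
    errors = spectra.errors / integrals[:, None]
    resolution = vanadium.counts / integrals[:, None]
    return spectra._like(counts, errors), resolution


# ---------------------------------------------------------------------------
# Per-Q lineshape fits
# ---------------------------------------------------------------------------

def _safe_weights(errors: np.ndarray) -> np.ndarray:
    err = np.where(errors > 0, errors, np.nanmax(errors) if np.nanmax(errors) > 0 else 1.0)
    return 1.0 / err


def _lineshape_hwhm(omega: np.ndarray, shape: np.ndarray) -> float:
    """Half width at half maximum of a sampled lineshape (resolution width)."""
    i0 = int(np.argmax(shape))
    half = shape[i0] / 2.0
    above = shape >= half
    return float(0.5 * (omega[above][-1] - omega[above][0]))


def _grid_scan_widths(
    data: np.ndarray,
    wt: np.ndarray,
    omega: np.ndarray,
    step: float,
    res_shape: np.ndarray,
    narrow_grid: np.ndarray,
    broad_grid: np.ndarray,
    extra_cols: list[np.ndarray],
    extra_nonneg: list[bool],
) -> tuple[float, float, np.ndarray, float]:
    """Coarse global search over (narrow, broad) Lorentzian widths.

    For fixed widths the composite model is linear in all amplitudes, so
    each grid point reduces to a bounded linear least-squares solve; this
    locates the global basin that a local optimizer started from a single
    guess frequently misses.  ``extra_cols`` are additional linear
    components (elastic lineshape, background bases, frozen buffer shape);
    ``extra_nonneg`` marks which of them are constrained to be ≥ 0.

    Returns (best_narrow, best_broad, best_amplitudes, best_cost).
    """
    from scipy.optimize import lsq_linear

    conv_cache = {
        g: convolve_resolution(lorentzian_density(omega, g), res_shape, step)
        for g in np.unique(np.concatenate([narrow_grid, broad_grid]))
    }
    n_extra = len(extra_cols)
    lo = np.zeros(2 + n_extra)
    hi = np.full(2 + n_extra, np.inf)
    for j, nn in enumerate(extra_nonneg):
        if not nn:
            lo[2 + j] = -np.inf
    best = (np.nan, np.nan, None, np.inf)
    yw = data * wt
    pairs = [
        (gn, gb)
        for gn in narrow_grid
        for gb in broad_grid
        if gb >= 1.2 * gn or (narrow_grid.size == 1 and broad_grid.size == 1)
    ]
    for gn, gb in pairs:
        cols = [conv_cache[gn], conv_cache[gb], *extra_cols]
        a = np.stack(cols, axis=1) * wt[:, None]
        sol = lsq_linear(a, yw, bounds=(lo, hi), method="bvls")
        if sol.cost < best[3]:
            best = (float(gn), float(gb), sol.x, float(sol.cost))
    return best


def _multistart(
    residual, params: lmfit.Parameters, n_starts: int, rng: np.random.Generator
) -> lmfit.minimizer.MinimizerResult:
    """Run leastsq from jittered starting points; keep the lowest chi²."""
    best = None
    for k in range(n_starts):
        trial = params.copy()
        if k > 0:
            for p in trial.values():
                if not p.vary:
                    continue
                jitter = p.value * (1.0 + 0.3 * rng.standard_normal())
                lo = p.min if np.isfinite(p.min) else -np.inf
                hi = p.max if np.isfinite(p.max) else np.inf
                p.value = float(np.clip(jitter, lo + abs(lo) * 1e-6 + 1e-9, hi))
        try:
            res = lmfit.minimize(residual, trial, method="leastsq")
        except Exception:  # non-convergence at one start is tolerated
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit starts failed")
    return best


def fit_buffer(
    buffer: QENSSpectra,
    resolution: np.ndarray,
    exclude_q2_window: tuple[float, float] | None = DEFAULT_DIP_WINDOW,
    n_starts: int = 3,
    seed: int = 0,
) -> BufferModel:
    """Fit the solvent with two resolution-convolved Lorentzians per Q.

    The narrow widths are then fitted globally with the jump-diffusion law
    (optionally excluding a Q² window around the coherent dip) and the broad
    width as a Q-independent constant.
    """
    if buffer.q_list.size < 5:
        raise ValueError("buffer fit needs at least 5 Q points")
    rng = np.random.default_rng(seed)
    omega = buffer.omega_grid
    step = buffer.omega_step
    nq = buffer.q_list.size

    g_n = np.full(nq, np.nan)
    g_n_err = np.full(nq, np.nan)
    g_b = np.full(nq, np.nan)
    g_b_err = np.full(nq, np.nan)
    ratio = np.full(nq, np.nan)
    amp_n = np.full(nq, np.nan)
    amp_b = np.full(nq, np.nan)
    ok = np.zeros(nq, dtype=bool)

    for iq in range(nq):
        data = buffer.counts[iq]
        wt = _safe_weights(buffer.errors[iq])
        res_shape = resolution[iq]
        res_hwhm = _lineshape_hwhm(omega, res_shape)

        gn0, gb0, amps, _ = _grid_scan_widths(
            data, wt, omega, step, res_shape,
            narrow_grid=np.geomspace(max(0.05 * res_hwhm, 1e-4), min(50 * res_hwhm, 1.0), 14),
            broad_grid=np.geomspace(res_hwhm, 5.0, 12),
            extra_cols=[np.ones_like(omega)],
            extra_nonneg=[True],
        )

        params = lmfit.Parameters()
        params.add("a_n", value=max(amps[0], 1e-12), min=0.0)
        params.add("g_n", value=gn0, min=1e-4, max=1.0)
        params.add("a_b", value=max(amps[1], 1e-12), min=0.0)
        params.add("width_ratio", value=min(max(gb0 / gn0, 1.21), 199.0), min=1.2, max=200.0)
        params.add("bg", value=max(amps[2], 0.0), min=0.0)

        def residual(p, _data=data, _wt=wt, _res=res_shape):
            gn = p["g_n"].value
            gb = gn * p["width_ratio"].value
            qel = p["a_n"].value * lorentzian_density(omega, gn) + p[
                "a_b"
            ].value * lorentzian_density(omega, gb)
            model = convolve_resolution(qel, _res, step) + p["bg"].value
            return (_data - model) * _wt

        try:
            out = _multistart(residual, params, n_starts, rng)
        except RuntimeError:
            logger.warning("buffer fit failed to converge at Q=%.3f; dropped", buffer.q_list[iq])
            continue
        ok[iq] = True
        g_n[iq] = out.params["g_n"].value
        g_n_err[iq] = out.params["g_n"].stderr or np.nan
        g_b[iq] = out.params["g_n"].value * out.params["width_ratio"].value
        # width_ratio stderr propagated crudely; the broad width is reduced
        # to a Q-average anyway
        g_b_err[iq] = (
            g_b[iq]
            * np.hypot(
                (out.params["g_n"].stderr or 0.0) / max(g_n[iq], 1e-12),
                (out.params["width_ratio"].stderr or 0.0)
                / max(out.params["width_ratio"].value, 1e-12),
            )
            or np.nan
        )
        a_n, a_b = out.params["a_n"].value, out.params["a_b"].value
        ratio[iq] = a_b / a_n if a_n > 0 else np.nan
        amp_n[iq], amp_b[iq] = a_n, a_b

    if np.count_nonzero(ok) < 4:
        raise ValueError("fewer than 4 Q points survived the buffer per-Q fits")

    jd, jd_err, used = fit_jump_diffusion_widths(
        buffer.q_list[ok], g_n[ok], g_n_err[ok], exclude_q2_window=exclude_q2_window
    )
    fitted_mask = np.zeros(nq, dtype=bool)
    fitted_mask[np.flatnonzero(ok)[used]] = True

    wb = 1.0 / np.where(np.isfinite(g_b_err[ok]) & (g_b_err[ok] > 0), g_b_err[ok], 1.0) ** 2
    rot_width = float(np.sum(wb * g_b[ok]) / np.sum(wb))
    rot_width_err = float(np.sqrt(1.0 / np.sum(wb))) if np.all(np.isfinite(g_b_err[ok])) else float(
        np.std(g_b[ok]) / np.sqrt(np.count_nonzero(ok))
    )

    return BufferModel(
        q_list=buffer.q_list.copy(),
        narrow_hwhm=g_n,
        narrow_hwhm_err=g_n_err,
        broad_hwhm=g_b,
        amplitude_ratio=float(np.nanmean(ratio)),
        jd=jd,
        jd_err=jd_err,
        rot_width=rot_width,
        rot_width_err=rot_width_err,
        fitted_q_mask=fitted_mask,
        narrow_amp=amp_n,
        broad_amp=amp_b,
        monitor=buffer.monitor,
    )


def _fit_sample_one_q(
    data: np.ndarray,
    wt: np.ndarray,
    omega: np.ndarray,
    step: float,
    res_shape: np.ndarray,
    buf_conv: np.ndarray | None,
    rng: np.random.Generator,
    n_starts: int,
    fixed_broad: float | None = None,
    fixed_narrow: float | None = None,
    fixed_bs: float | None = None,
) -> tuple[lmfit.minimizer.MinimizerResult, float, list[str]]:
    """One-Q composite fit: grid scan over widths, then local polish.

    With ``fixed_broad`` set, the broad Lorentzian width is frozen (the
    second pass of the Q-constrained protocol) and only the narrow width
    stays nonlinear; with ``fixed_narrow`` set as well, only the linear
    amplitudes remain free (the final amplitude pass).  ``fixed_bs``
    freezes the buffer scale at a value pooled across Q.
    """
    if fixed_bs is not None and buf_conv is not None:
        data = data - fixed_bs * buf_conv
        buf_conv = None
    res_hwhm = _lineshape_hwhm(omega, res_shape)
    # identifiability floor: a Lorentzian much narrower than the resolution
    # is indistinguishable from the elastic line (such motion is "immobile"
    # on the instrument's time scale)
    g_floor = 0.25 * res_hwhm

    extra_cols = [res_shape, np.ones_like(omega), omega]
    extra_nonneg = [True, True, False]
    if buf_conv is not None:
        extra_cols.append(buf_conv)
        extra_nonneg.append(True)

    if fixed_narrow is None:
        narrow_grid = np.geomspace(max(0.3 * res_hwhm, 1e-4), min(50 * res_hwhm, 2.0), 14)
    else:
        narrow_grid = np.array([max(fixed_narrow, 1e-6)])
    if fixed_broad is None:
        broad_grid = np.geomspace(res_hwhm, 3.0, 12)
    else:
        broad_grid = np.array([fixed_broad])
    gn0, gb0, amps, _ = _grid_scan_widths(
        data, wt, omega, step, res_shape,
        narrow_grid=narrow_grid,
        broad_grid=broad_grid,
        extra_cols=extra_cols,
        extra_nonneg=extra_nonneg,
    )

    params = lmfit.Parameters()
    params.add("a0", value=max(amps[2], 1e-12), min=0.0)
    params.add("a_nar", value=max(amps[0], 1e-12), min=0.0)
    if fixed_narrow is None:
        params.add("g_nar", value=max(gn0, g_floor * 1.05), min=g_floor, max=2.0)
    else:
        params.add("g_nar", value=max(fixed_narrow, 1e-6), vary=False)
    params.add("a_brd", value=max(amps[1], 1e-12), min=0.0)
    if fixed_broad is None:
        params.add("g_brd", value=max(gb0, 1.21 * gn0), min=1.2 * g_floor, max=3.0)
    else:
        params.add("g_brd", value=fixed_broad, vary=False)
    params.add("b0", value=max(amps[3], 0.0), min=0.0)
    params.add("b1", value=float(amps[4]))
    if buf_conv is not None:
        params.add("bs", value=max(amps[5], 0.0), min=0.0)

    def residual(p, _data=data, _wt=wt, _res=res_shape, _buf=buf_conv):
        qel = p["a_nar"].value * lorentzian_density(omega, p["g_nar"].value) + p[
            "a_brd"
        ].value * lorentzian_density(omega, p["g_brd"].value)
        model = (
            p["a0"].value * _res
            + convolve_resolution(qel, _res, step)
            + p["b0"].value
            + p["b1"].value * omega
        )
        if _buf is not None:
            model = model + p["bs"].value * _buf
        return (_data - model) * _wt

    out = _multistart(residual, params, n_starts, rng)

    flags: list[str] = []
    pr = out.params
    if pr["g_brd"].vary or pr["g_nar"].vary:
        if pr["g_brd"].value < 1.2 * pr["g_nar"].value * 1.0001:
            flags.append("width_degenerate")
    if pr["g_nar"].vary and (
        pr["g_nar"].value <= g_floor * 1.001 or pr["g_nar"].value >= 2.0 * 0.999
    ):
        flags.append("g_nar_at_bound")
    if pr["a0"].value <= 1e-9:
        flags.append("elastic_degenerate")
    return out, g_floor, flags


def _global_width_fit(
    sample: QENSSpectra,
    resolution: np.ndarray,
    buf_convs: list,
    jd_init: JumpDiffusionParams,
    gamma_b_init: float,
    bs_init: float = 0.0,
    bs_bounds: tuple[float, float] = (0.0, 100.0),
    bs_fixed: float | None = None,
) -> tuple[JumpDiffusionParams, float, float, np.ndarray]:
    """Joint fit of (D_T, τ₀, Γ_broad, buffer scale) over all Q spectra.

    For any trial parameter set the per-Q model is linear in its remaining
    amplitudes, so they are projected out with bounded linear least squares
    and only a handful of nonlinear parameters remain, constrained by every
    spectrum simultaneously.  The solvent scale is one shared number — the
    buffer volume fraction does not depend on Q once detector efficiency is
    normalized out — which breaks the near-degeneracy between the frozen
    buffer pair and the sample's own Lorentzians that per-Q scales leave
    open.  Returns (jd, Γ_broad, buffer_scale, standard errors).
    """
    from scipy.optimize import least_squares, lsq_linear

    omega = sample.omega_grid
    step = sample.omega_step
    nq = sample.q_list.size
    wts = [_safe_weights(sample.errors[iq]) for iq in range(nq)]
    has_buffer = any(bc is not None for bc in buf_convs) and bs_fixed is None
    n_theta = 4 if has_buffer else 3

    def residuals(theta: np.ndarray) -> np.ndarray:
        d_t, tau0, g_b = theta[:3]
        bs = theta[3] if has_buffer else (bs_fixed or 0.0)
        jd = JumpDiffusionParams(D_T=d_t, tau0=tau0)
        out = []
        for iq in range(nq):
            gn = float(jump_diffusion_hwhm(jd, sample.q_list[iq]))
            cols = [
                convolve_resolution(
                    lorentzian_density(omega, max(gn, 1e-6)), resolution[iq], step
                ),
                convolve_resolution(lorentzian_density(omega, g_b), resolution[iq], step),
                resolution[iq],
                np.ones_like(omega),
                omega,
            ]
            lo = [0.0, 0.0, 0.0, 0.0, -np.inf]
            y_iq = sample.counts[iq]
            if buf_convs[iq] is not None:
                y_iq = y_iq - bs * buf_convs[iq]
            a = np.stack(cols, axis=1) * wts[iq][:, None]
            y = y_iq * wts[iq]
            sol = lsq_linear(a, y, bounds=(lo, np.inf), method="bvls")
            out.append(a @ sol.x - y)
        return np.concatenate(out)

    x0 = [
        min(max(jd_init.D_T, 1e-3), 9.9),
        min(max(jd_init.tau0, 1e-3), 99.0),
        min(max(gamma_b_init, 1e-3), 2.9),
    ]
    lo_b = [1e-4, 0.0, 1e-3]
    hi_b = [10.0, 100.0, 3.0]
    if has_buffer:
        x0.append(min(max(bs_init, bs_bounds[0]), bs_bounds[1]))
        lo_b.append(bs_bounds[0])
        hi_b.append(bs_bounds[1])
    x0 = np.array(x0)
    # deliberately different starts guard against the occasional local
    # minimum of the projected landscape
    starts = [x0, x0.copy(), x0.copy()]
    starts[1][:3] = [0.3, 4.0, 0.5]
    starts[2][:3] = x0[:3] * [2.0, 0.5, 0.75]
    if has_buffer:
        span = bs_bounds[1] - bs_bounds[0]
        starts[1][3] = bs_bounds[0] + 0.25 * span
        starts[2][3] = bs_bounds[0] + 0.75 * span
    best = None
    for start in starts:
        sol = least_squares(
            residuals,
            np.clip(start, lo_b, hi_b),
            bounds=(lo_b, hi_b),
            diff_step=1e-3,
            xtol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    # parameter errors from the Gauss-Newton approximation at the optimum
    dof = max(best.fun.size - n_theta, 1)
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * (2.0 * best.cost / dof)
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        errs = np.full(n_theta, np.nan)
    bs_out = float(best.x[3]) if has_buffer else float(bs_fixed or 0.0)
    return (
        JumpDiffusionParams(D_T=float(best.x[0]), tau0=float(best.x[1])),
        float(best.x[2]),
        bs_out,
        errs,
    )


def fit_sample(
    sample: QENSSpectra,
    buffer_model: BufferModel | None,
    resolution: np.ndarray,
    n_starts: int = 3,
    seed: int = 0,
    constrain_broad: bool = True,
    solvent_fill: float | None = None,
) -> SampleFit:
    """Constrained per-Q fit of a protein sample spectrum.

    Model at each Q: one free buffer scale multiplying the frozen buffer
    Lorentzian pair (per-Q narrow width, Q-averaged broad width, fixed
    internal intensity ratio), a resolution-shaped elastic line, two free
    sample Lorentzians and a linear background; quasi-elastic terms are
    convolved with the per-Q resolution.

    With ``constrain_broad`` (default) the fit is run twice, mirroring the
    rotational model's Q-independent width: free per-Q fits first, then a
    robust (median) global broad width is frozen into a second per-Q pass.
    This stabilizes the elastic/narrow/broad intensity split on which the
    EISF depends.

    ``solvent_fill`` is the sample's solvent content relative to the neat
    buffer measurement (monitor-normalized), known from the sample's
    gravimetric composition.  When supplied it pins the buffer scale —
    essential when buffer and sample relaxation rates overlap, where the
    spectra alone carry almost no information on the attribution; when
    None, the scale is fitted within a physically plausible window.
    """
    omega = sample.omega_grid
    step = sample.omega_step
    nq = sample.q_list.size
    rng = np.random.default_rng(seed)

    if buffer_model is not None and (
        buffer_model.q_list.size != nq or not np.allclose(buffer_model.q_list, sample.q_list)
    ):
        raise ValueError("buffer model Q list does not match the sample")

    # the buffer component is carried on the shared monitor-normalized
    # intensity scale: with per-Q fitted buffer intensities scaled by the
    # monitor ratio, its coefficient in the sample fit is the solvent fill
    # fraction relative to the neat buffer measurement, a quantity bounded
    # by physics (a hydrated sample holds neither zero solvent nor more
    # than the neat buffer)
    physical_bs = (
        buffer_model is not None
        and buffer_model.narrow_amp is not None
        and np.any(np.isfinite(buffer_model.narrow_amp))
    )
    mon_ratio = sample.monitor / buffer_model.monitor if physical_bs else 1.0
    buf_convs: list[np.ndarray | None] = []
    for iq in range(nq):
        if buffer_model is not None and np.isfinite(buffer_model.narrow_hwhm[iq]):
            if physical_bs and np.isfinite(buffer_model.narrow_amp[iq]):
                buf_shape = mon_ratio * (
                    buffer_model.narrow_amp[iq]
                    * lorentzian_density(omega, buffer_model.narrow_hwhm[iq])
                    + buffer_model.broad_amp[iq]
                    * lorentzian_density(omega, buffer_model.rot_width)
                )
            else:
                buf_shape = lorentzian_density(omega, buffer_model.narrow_hwhm[iq]) + (
                    buffer_model.amplitude_ratio
                    * lorentzian_density(omega, buffer_model.rot_width)
                )
            buf_convs.append(convolve_resolution(buf_shape, resolution[iq], step))
        else:
            buf_convs.append(None)
    # without composition knowledge the fill is fitted inside a physically
    # plausible window (a hydrated sample holds neither zero solvent nor
    # much more than the neat buffer)
    bs_bounds = (0.6, 1.1) if physical_bs else (0.0, 100.0)
    bs_known = solvent_fill if (physical_bs and solvent_fill is not None) else None

    def run_pass(
        fixed_broad: np.ndarray | None,
        fixed_narrow: np.ndarray | None = None,
        fixed_bs: float | None = None,
    ):
        outs, floors, flag_lists = [], [], []
        for iq in range(nq):
            fb = None if fixed_broad is None else float(fixed_broad[iq])
            fn = None if fixed_narrow is None else float(fixed_narrow[iq])
            try:
                out, floor, fl = _fit_sample_one_q(
                    sample.counts[iq],
                    _safe_weights(sample.errors[iq]),
                    omega, step, resolution[iq], buf_convs[iq],
                    rng, n_starts, fixed_broad=fb, fixed_narrow=fn, fixed_bs=fixed_bs,
                )
            except RuntimeError:
                outs.append(None)
                floors.append(np.nan)
                flag_lists.append(["no_convergence"])
                continue
            outs.append(out)
            floors.append(floor)
            flag_lists.append(fl)
        return outs, floors, flag_lists

    outs, floors, flag_lists = run_pass(None, fixed_bs=bs_known)

    if constrain_broad:
        broads = np.array(
            [
                out.params["g_brd"].value if out is not None else np.nan
                for out, fl in zip(outs, flag_lists)
            ]
        )
        clean = np.isfinite(broads) & np.array(
            ["width_degenerate" not in fl for fl in flag_lists]
        )
        if np.count_nonzero(clean) >= 3:
            gamma_b = float(np.median(broads[clean]))
            spread = float(
                1.4826 * np.median(np.abs(broads[clean] - gamma_b))
                / np.sqrt(np.count_nonzero(clean))
            )
            outs2, floors2, flags2 = run_pass(np.full(nq, gamma_b), fixed_bs=bs_known)
            # keep the constrained pass; per-Q broad errors become the
            # robust error of the global constant
            outs, floors, flag_lists = outs2, floors2, flags2
            broad_err_global = max(spread, 1e-6)
        else:
            gamma_b, broad_err_global = None, None
    else:
        gamma_b, broad_err_global = None, None

    # free narrow widths and their errors come from the width-measuring
    # pass; a final amplitude-only pass (below) may refine the intensities
    narrow_vals = np.array(
        [out.params["g_nar"].value if out is not None else np.nan for out in outs]
    )
    narrow_errs = np.array(
        [
            (out.params["g_nar"].stderr or np.nan) if out is not None else np.nan
            for out in outs
        ]
    )
    pass2_flags = [list(fl) for fl in flag_lists]

    if constrain_broad and gamma_b is not None:
        # tie the widths together across Q — narrow through the
        # jump-diffusion law, broad as one constant — by a global
        # variable-projection fit of all spectra (amplitudes solved
        # linearly per Q), then refit amplitudes only with the widths
        # frozen: the elastic/quasi-elastic split (the EISF) is then a
        # well-conditioned linear problem at every Q
        bad = {"no_convergence", "width_degenerate", "g_nar_at_bound", "elastic_degenerate"}
        wclean = np.isfinite(narrow_vals) & np.array(
            [not (bad & set(fl)) for fl in pass2_flags]
        )
        try:
            jd_init, _, _ = fit_jump_diffusion_widths(
                sample.q_list[wclean], narrow_vals[wclean], narrow_errs[wclean]
            )
            # the solvent volume fraction is the same at every Q once the
            # detector efficiency is normalized out, so the buffer scale is
            # one shared parameter of the global fit
            bs_pass2 = np.array(
                [
                    out.params["bs"].value if out is not None and "bs" in out.params else np.nan
                    for out in outs
                ]
            )
            bs_init = (
                float(np.nanmedian(bs_pass2)) if np.any(np.isfinite(bs_pass2)) else 0.0
            )
            jd_glob, gamma_b_glob, bs_glob, glob_errs = _global_width_fit(
                sample, resolution, buf_convs, jd_init, gamma_b, bs_init,
                bs_bounds=bs_bounds, bs_fixed=bs_known,
            )
            smooth = np.asarray(jump_diffusion_hwhm(jd_glob, sample.q_list))
            bs_global = bs_glob if any(bc is not None for bc in buf_convs) else None
            outs3, floors3, flags3 = run_pass(
                np.full(nq, gamma_b_glob),
                np.maximum(smooth, 1e-6),
                fixed_bs=bs_global,
            )
            outs, floors, flag_lists = outs3, floors3, flags3
            gamma_b = gamma_b_glob
            global_widths = {
                "D_T": jd_glob.D_T,
                "D_T_err": float(glob_errs[0]),
                "tau0": jd_glob.tau0,
                "tau0_err": float(glob_errs[1]),
                "broad": gamma_b_glob,
                "broad_err": float(glob_errs[2]),
                "buffer_scale": bs_glob,
            }
        except (ValueError, RuntimeError):
            bs_global = None  # keep the pass-2 results
            global_widths = None
    else:
        bs_global = None
        global_widths = None

    cols = [
        "buffer_scale", "elastic_amplitude", "elastic_amplitude_err",
        "narrow_hwhm", "narrow_hwhm_err", "narrow_amplitude", "narrow_amplitude_err",
        "broad_hwhm", "broad_hwhm_err", "broad_amplitude", "broad_amplitude_err",
        "bg_slope", "bg_intercept", "chi2",
    ]
    store = {c: np.full(nq, np.nan) for c in cols}
    covars: list = [None] * nq
    flags: list[list[str]] = [
        sorted(set(p2) | set(p3)) for p2, p3 in zip(pass2_flags, flag_lists)
    ]

    for iq, out in enumerate(outs):
        if out is None:
            continue
        pr = out.params
        if "bs" in pr:
            store["buffer_scale"][iq] = pr["bs"].value
        else:
            store["buffer_scale"][iq] = bs_global if bs_global is not None else 0.0
        store["elastic_amplitude"][iq] = pr["a0"].value
        store["elastic_amplitude_err"][iq] = pr["a0"].stderr or np.nan
        if pr["g_nar"].vary:
            store["narrow_hwhm"][iq] = pr["g_nar"].value
            store["narrow_hwhm_err"][iq] = pr["g_nar"].stderr or np.nan
        else:
            # width from the free (measuring) pass; the frozen value only
            # conditioned the amplitude refit
            store["narrow_hwhm"][iq] = narrow_vals[iq]
            store["narrow_hwhm_err"][iq] = narrow_errs[iq]
        store["narrow_amplitude"][iq] = pr["a_nar"].value
        store["narrow_amplitude_err"][iq] = pr["a_nar"].stderr or np.nan
        store["broad_hwhm"][iq] = pr["g_brd"].value
        if pr["g_brd"].vary:
            store["broad_hwhm_err"][iq] = pr["g_brd"].stderr or np.nan
        else:
            store["broad_hwhm_err"][iq] = broad_err_global
        store["broad_amplitude"][iq] = pr["a_brd"].value
        store["broad_amplitude_err"][iq] = pr["a_brd"].stderr or np.nan
        store["bg_slope"][iq] = pr["b1"].value
        store["bg_intercept"][iq] = pr["b0"].value
        store["chi2"][iq] = out.redchi

        # covariance of the three amplitudes, for EISF error propagation
        if out.covar is not None:
            names = [n for n in out.params if out.params[n].vary]
            idx = {n: i for i, n in enumerate(names)}
            try:
                sel = [idx["a0"], idx["a_nar"], idx["a_brd"]]
                covars[iq] = out.covar[np.ix_(sel, sel)]
            except KeyError:
                pass

    return SampleFit(
        q_list=sample.q_list.copy(),
        buffer_scale=store["buffer_scale"],
        elastic_amplitude=store["elastic_amplitude"],
        elastic_amplitude_err=store["elastic_amplitude_err"],
        narrow_hwhm=store["narrow_hwhm"],
        narrow_hwhm_err=store["narrow_hwhm_err"],
        narrow_amplitude=store["narrow_amplitude"],
        narrow_amplitude_err=store["narrow_amplitude_err"],
        broad_hwhm=store["broad_hwhm"],
        broad_hwhm_err=store["broad_hwhm_err"],
        broad_amplitude=store["broad_amplitude"],
        broad_amplitude_err=store["broad_amplitude_err"],
        bg_slope=store["bg_slope"],
        bg_intercept=store["bg_intercept"],
        chi2=store["chi2"],
        flags=flags,
        covar=covars,
        global_widths=global_widths,
    )


# ---------------------------------------------------------------------------
# EISF and transport parameters
# ---------------------------------------------------------------------------

def compute_eisf(fit: SampleFit) -> EisfCurve:
    """EISF A₀(Q) = elastic / (elastic + quasi-elastic sample amplitudes).

    The buffer contribution and the background are excluded: the buffer is
    solvent, not sample, and the background carries no sample dynamics.
    Q points whose fit was flagged degenerate (collapsed widths, elastic
    intensity pinned at zero) are dropped; errors are propagated to first
    order using the fitted amplitude covariance where available.
    """
    bad_flags = {"no_convergence", "elastic_degenerate", "width_degenerate"}
    good = np.isfinite(fit.elastic_amplitude) & np.array(
        [not (bad_flags & set(fl)) for fl in fit.flags]
    )
    if np.count_nonzero(good) < 5:
        raise ValueError("EISF needs at least 5 converged Q points")
    a0 = fit.elastic_amplitude[good]
    an = fit.narrow_amplitude[good]
    ab = fit.broad_amplitude[good]
    denom = a0 + an + ab
    if np.any(denom <= 0):
        raise ValueError("zero total intensity in EISF denominator")
    eisf = a0 / denom

    # d(eisf)/d(a0, an, ab) = ((an+ab), -a0, -a0) / denom^2
    err = np.full(eisf.shape, np.nan)
    idx_good = np.flatnonzero(good)
    for j, iq in enumerate(idx_good):
        grad = np.array([an[j] + ab[j], -a0[j], -a0[j]]) / denom[j] ** 2
        cov = fit.covar[iq] if fit.covar is not None else None
        if cov is not None and np.all(np.isfinite(cov)):
            err[j] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        else:
            sig = np.array(
                [
                    fit.elastic_amplitude_err[iq],
                    fit.narrow_amplitude_err[iq],
                    fit.broad_amplitude_err[iq],
                ]
            )
            sig = np.where(np.isfinite(sig), sig, 0.0)
            err[j] = float(np.sqrt(np.sum((grad * sig) ** 2)))
    return EisfCurve(q=fit.q_list[good], a0=eisf, a0_error=err)


def fit_eisf(curve: EisfCurve) -> tuple[float, float, float, float, list[str]]:
    """Fit p + (1-p)[3j₁(QR)/QR]² to an EISF curve.

    Returns (p, p_err, R, R_err, flags).  Bounds p ∈ [0, 1], R ∈ (0.1, 20) Å;
    a solution pinned at a bound, or an R made unidentifiable by p → 1, is
    flagged rather than rejected.
    """
    usable = np.isfinite(curve.a0_error) & (curve.a0_error > 0)
    if np.count_nonzero(usable) >= 5:
        # a point with no defensible uncertainty (bound-pinned, singular
        # covariance) carries no usable information; excluding it beats
        # giving it unit weight
        w = np.where(usable, 1.0 / np.where(usable, curve.a0_error, 1.0), 0.0)
    else:
        # exact (noise-free) fits propagate ~zero uncertainty; fall back to
        # unweighted least squares over all finite points
        usable = np.isfinite(curve.a0)
        if np.count_nonzero(usable) < 5:
            raise ValueError("EISF fit needs at least 5 usable points")
        w = usable.astype(float)

    def residual(pars):
        from .scattering import ConfinedRotationParams

        model = eisf_with_immobile(
            ConfinedRotationParams(p=pars["p"].value, R=pars["R"].value), curve.q
        )
        return (curve.a0 - model) * w

    # the (p, R) surface can hold two local minima (high-p/small-R vs
    # low-p/large-R); start from a radius grid and keep the global optimum
    p_init = max(min(float(curve.a0.min()), 0.99), 0.01)
    out = None
    for r_start in np.geomspace(0.5, 8.0, 8):
        params = lmfit.Parameters()
        params.add("p", value=p_init, min=0.0, max=1.0)
        params.add("R", value=r_start, min=0.1, max=20.0)
        trial = lmfit.minimize(residual, params, method="leastsq")
        if out is None or trial.chisqr < out.chisqr:
            out = trial
    p = out.params["p"].value
    r = out.params["R"].value
    p_err = out.params["p"].stderr or float("nan")
    r_err = out.params["R"].stderr or float("nan")

    flags: list[str] = []
    if p >= 0.999 or p <= 1e-3:
        flags.append("p_at_bound")
    if r <= 0.1 * 1.01 or r >= 20.0 * 0.99:
        flags.append("R_at_bound")
    if p >= 0.99 or (np.isfinite(r_err) and r_err > r):
        flags.append("R_unidentifiable")
    return float(p), float(p_err), float(r), float(r_err), flags


def fit_jump_diffusion_widths(
    q: np.ndarray,
    hwhm: np.ndarray,
    hwhm_err: np.ndarray | None = None,
    exclude_q2_window: tuple[float, float] | None = None,
) -> tuple[JumpDiffusionParams, tuple[float, float], np.ndarray]:
    """Weighted fit of Γ(Q) = ħ D_T Q²/(1 + D_T Q² τ₀) to measured widths.

    Returns the fitted parameters, their standard errors and the boolean mask
    of points used (after optional exclusion of a Q² window, e.g. around a
    coherent-scattering dip).
    """
    q = np.asarray(q, dtype=float)
    hwhm = np.asarray(hwhm, dtype=float)
    use = np.isfinite(hwhm) & np.isfinite(q)
    if exclude_q2_window is not None:
        lo, hi = exclude_q2_window
        use &= ~((q**2 >= lo) & (q**2 <= hi))
    if np.count_nonzero(use) < 4:
        raise ValueError("fewer than 4 usable points for the jump-diffusion fit")
    qs, gs = q[use], hwhm[use]
    if hwhm_err is not None:
        errs = np.asarray(hwhm_err, dtype=float)[use]
        ok_err = np.isfinite(errs) & (errs > 0)
        if np.any(ok_err):
            # substitute the median error for points without one, and cap
            # relative weights so a numerically-zero stderr cannot swamp
            # the fit
            med = float(np.median(errs[ok_err]))
            errs = np.where(ok_err, errs, med)
            w = 1.0 / np.maximum(errs, med / 20.0)
        else:
            w = np.ones_like(gs)
        # normalize so the robust loss sees residuals in σ-like units even
        # when the stated errors are tiny (noise-free limit)
        w = w / np.median(w)
    else:
        w = np.ones_like(gs)

    d0 = min(max(gs[0] / (HBAR_MEV_PS * qs[0] ** 2), 1e-4), 9.0)
    tau0_0 = min(max(HBAR_MEV_PS / max(gs.max(), 1e-6) * 0.5, 1e-3), 90.0)
    params = lmfit.Parameters()
    # upper bounds are far above any liquid-state value; they only stop the
    # degenerate runaway where flat widths make D_T unidentifiable
    params.add("D_T", value=d0, min=1e-6, max=10.0)
    params.add("tau0", value=tau0_0, min=0.0, max=100.0)

    def residual(p):
        model = jump_diffusion_hwhm(
            JumpDiffusionParams(D_T=p["D_T"].value, tau0=p["tau0"].value), qs
        )
        return (gs - model) * w

    # soft-L1 loss caps the influence of an occasional wrong-basin width
    out = lmfit.minimize(
        residual, params, method="least_squares", loss="soft_l1", f_scale=2.0
    )
    jd = JumpDiffusionParams(D_T=out.params["D_T"].value, tau0=out.params["tau0"].value)
    errs = (
        out.params["D_T"].stderr or float("nan"),
        out.params["tau0"].stderr or float("nan"),
    )
    return jd, errs, use


def fit_transport(
    fit: SampleFit,
    exclude_q2_window: tuple[float, float] | None = None,
    prefer_global: bool = True,
) -> TransportParams:
    """Transport parameters from a converged sample fit.

    Narrow widths → jump-diffusion (D_T on the 1e-5 cm²/s scale, τ₀ in ps);
    broad widths → Q-independent constant Γ, reported as D_R = Γ/2.
    When the sample fit carried out the jointly constrained width fit, its
    estimates are reported (``prefer_global``): the per-Q width curve is
    much noisier and its jump-diffusion fit occasionally degenerates when
    the widths come out Q-flat.  Q points flagged as width-degenerate are
    excluded from the per-Q route.
    """
    if prefer_global and fit.global_widths is not None:
        gw = fit.global_widths
        # a D_T pinned at its upper bound signals the flat-width degeneracy
        # (the data cannot resolve the sub-resolution low-Q widths); fall
        # through to the per-Q route in that case
        if gw["D_T"] < 9.9:
            return TransportParams(
                D_T=d_to_reported_scale(gw["D_T"]),
                D_T_err=d_to_reported_scale(gw["D_T_err"]),
                tau0=gw["tau0"],
                tau0_err=gw["tau0_err"],
                D_R=gw["broad"] / 2.0,
                D_R_err=gw["broad_err"] / 2.0,
            )
    bad_flags = {"no_convergence", "width_degenerate", "g_nar_at_bound", "elastic_degenerate"}
    clean = np.array(
        [np.isfinite(g) and not (bad_flags & set(fl)) for g, fl in zip(fit.narrow_hwhm, fit.flags)]
    )
    if np.count_nonzero(clean) < 4:
        raise ValueError("fewer than 4 usable Q points for transport fits")
    jd, (d_err, t_err), _ = fit_jump_diffusion_widths(
        fit.q_list[clean],
        fit.narrow_hwhm[clean],
        fit.narrow_hwhm_err[clean],
        exclude_q2_window=exclude_q2_window,
    )
    gb = fit.broad_hwhm[clean]
    gb_err = fit.broad_hwhm_err[clean]
    w = 1.0 / np.where(np.isfinite(gb_err) & (gb_err > 0), gb_err, 1.0) ** 2
    gamma_rot = float(np.sum(w * gb) / np.sum(w))
    if np.all(np.isfinite(gb_err) & (gb_err > 0)):
        gamma_rot_err = float(np.sqrt(1.0 / np.sum(w)))
    else:
        gamma_rot_err = float(np.std(gb, ddof=1) / np.sqrt(gb.size))
    return TransportParams(
        D_T=d_to_reported_scale(jd.D_T),
        D_T_err=d_to_reported_scale(d_err) if np.isfinite(d_err) else float("nan"),
        tau0=jd.tau0,
        tau0_err=t_err,
        D_R=gamma_rot / 2.0,
        D_R_err=gamma_rot_err / 2.0,
    )
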