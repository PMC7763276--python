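"""Forward models that generate every input the analysis pipelines consume.

All generators draw from a :class:`numpy.random.Generator` seeded
explicitly, so datasets are bit-reproducible.  The QENS generator composes
exactly the spectral model the fitting side assumes — Debye–Waller-damped
elastic line plus Lorentzians, convolved with a Gaussian instrument
resolution, with Poisson counting noise — so that every injected parameter
is recoverable by the corresponding pipeline, which is the module's core
contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import FWHM_TO_SIGMA, HBAR_MEV_PS
from .elastic import ElasticScan
from .md import Trajectory
from .qens import QENSSpectra
from .scattering import (
    CompositeSpectrumModel,
    ConfinedRotationParams,
    DebyeWallerFactor,
    JumpDiffusionParams,
    LorentzianComponent,
    convolve_resolution,
    eisf_with_immobile,
    evaluate_composite,
    impulse_density,
    jump_diffusion_hwhm,
    rotational_hwhm,
)

__all__ = [
    "InstrumentProfile",
    "GroundTruthCondition",
    "make_instrument",
    "gen_qens_dataset",
    "gen_elastic_scan",
    "gen_trajectory",
    "gen_hbond_toy",
    "REFERENCE_CONDITIONS",
]


# ---------------------------------------------------------------------------
# Instruments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstrumentProfile:
    """Spectrometer description used by the generators.

    ``resolution_hwhm`` follows from the accessible time window through the
    energy–time uncertainty relation, ΔE ≈ ħ/Δt.
    """

    label: str
    omega_range: tuple[float, float]  # meV
    omega_step: float  # meV
    resolution_hwhm: float  # meV
    q_grid: np.ndarray  # 1/Å
    time_window: float  # ps

    def __post_init__(self) -> None:
        if self.resolution_hwhm <= 0:
            raise ValueError("resolution_hwhm must be positive")
        object.__setattr__(self, "q_grid", np.asarray(self.q_grid, dtype=float))

    @property
    def omega_grid(self) -> np.ndarray:
        lo, hi = self.omega_range
        n = int(round((hi - lo) / self.omega_step)) + 1
        return lo + self.omega_step * np.arange(n)

    def resolution_density(self, omega: np.ndarray) -> np.ndarray:
        """Unit-normalized Gaussian resolution lineshape on the grid."""
        sigma = 2.0 * self.resolution_hwhm * FWHM_TO_SIGMA
        g = np.exp(-0.5 * (omega / sigma) ** 2)
        return g / np.trapezoid(g, omega)


#: default Q grid: 12 detectors spanning the typical time-of-flight range
_DEFAULT_Q = np.linspace(0.4, 2.0, 12)

_PRESETS = {
    # time window (ps); omega range and step scaled to the resolution
    "in6_like": dict(time_window=20.0, omega_range=(-5.0, 5.0), omega_step=0.01),
    "in13_like": dict(time_window=100.0, omega_range=(-1.0, 1.0), omega_step=0.002),
    "in16_like": dict(time_window=1000.0, omega_range=(-0.1, 0.1), omega_step=0.0002),
}


def make_instrument(label: str, **overrides) -> InstrumentProfile:
    """Build an instrument profile from a preset label or explicit fields.

    Presets ``in6_like`` / ``in13_like`` / ``in16_like`` model cold
    time-of-flight and thermal/high-resolution backscattering spectrometers
    with time windows of 20 ps, 100 ps and 1 ns, i.e. resolution HWHM
    ħ/Δt ≈ 0.0329, 0.0066 and 0.00066 meV.
    """
    if label in _PRESETS:
        cfg = dict(_PRESETS[label])
        cfg.update(overrides)
        cfg.setdefault("resolution_hwhm", HBAR_MEV_PS / cfg["time_window"])
        cfg.setdefault("q_grid", _DEFAULT_Q.copy())
        return InstrumentProfile(label=label, **cfg)
    required = {"omega_range", "omega_step", "resolution_hwhm", "q_grid", "time_window"}
    missing = required - overrides.keys()
    if missing:
        raise ValueError(
            f"unknown preset {label!r}; a custom profile must specify {sorted(missing)}"
        )
    return InstrumentProfile(label=label, **overrides)


# ---------------------------------------------------------------------------
# Ground truth for a measurement condition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthCondition:
    """Complete set of parameters behind one synthetic measurement.

    ``buffer_in_sample`` sets the buffer contribution to the sample
    spectrum relative to the protein intensity; for D₂O solvent against a
    protonated protein the incoherent cross-sections make this modest.
    ``narrow_fraction`` splits the quasi-elastic protein intensity between
    the narrow (translational) and broad (rotational) Lorentzians.
    """

    concentration: float  # sucrose wt%
    buffer_jd: JumpDiffusionParams
    buffer_rot_width: float  # meV
    buffer_ratio: float  # broad/narrow buffer intensity
    sample_jd: JumpDiffusionParams
    sample_rot: ConfinedRotationParams
    u2: float = 0.3  # Å², Debye–Waller MSD at the measuring temperature
    bg_slope: float = 0.0  # intensity per meV, before count scaling
    bg_intercept: float = 0.002
    peak_counts: float | None = 1e4  # expected counts at elastic max; None = noise-free
    buffer_in_sample: float = 0.2  # buffer integral relative to protein integral
    empty_level: float = 0.01  # flat empty-cell level relative to protein peak
    narrow_fraction: float = 0.5
    #: solvent content of the sample relative to the neat buffer cell
    #: (protein excluded volume displaces some solvent)
    solvent_fill: float = 0.9
    seed: int = 0


def _ref_condition(conc, b_dt, b_tau, s_dt, s_tau, p, r, d_r) -> GroundTruthCondition:
    return GroundTruthCondition(
        concentration=conc,
        buffer_jd=JumpDiffusionParams(D_T=b_dt, tau0=b_tau),
        buffer_rot_width=0.4,
        buffer_ratio=0.5,
        sample_jd=JumpDiffusionParams(D_T=s_dt, tau0=s_tau),
        sample_rot=ConfinedRotationParams(p=p, R=r, D_R=d_r),
    )


#: Ground-truth conditions emulating an aqueous enzyme titrated with
#: sucrose at 310 K on a 20 ps time-of-flight instrument: D₂O buffer
#: jump-diffusion slows with sugar, the protein's immobile fraction and
#: rotational rate grow, while its confinement radius stays ~2.1-2.3 Å.
REFERENCE_CONDITIONS: dict[float, GroundTruthCondition] = {
    0.0: _ref_condition(0.0, 0.117, 3.3, 0.29, 5.5, 0.726, 2.11, 0.24),
    5.0: _ref_condition(5.0, 0.089, 5.2, 0.21, 3.8, 0.758, 2.24, 0.36),
    10.0: _ref_condition(10.0, 0.073, 5.9, 0.27, 2.3, 0.798, 2.30, 0.40),
    15.0: _ref_condition(15.0, 0.061, 5.5, 0.27, 2.3, 0.798, 2.30, 0.40),
}


# ---------------------------------------------------------------------------
# QENS spectra
# ---------------------------------------------------------------------------

def _apply_counting(
    clean: np.ndarray, scale: float, rng: np.random.Generator, noise: bool
) -> tuple[np.ndarray, np.ndarray]:
    expected = clean * scale
    counts = rng.poisson(expected).astype(float) if noise else expected
    # report the true counting uncertainty sqrt(E[n]); basing sigma on the
    # observed counts instead would systematically overweight downward
    # fluctuations in low-count bins and bias the weighted fits
    errors = np.sqrt(np.maximum(expected, 1.0))
    return counts, errors


def gen_qens_dataset(
    truth: GroundTruthCondition, instrument: InstrumentProfile
) -> dict[str, QENSSpectra]:
    """Generate a {sample, buffer, empty, vanadium} quadruple of spectra.

    The vanadium is the Gaussian resolution lineshape; the buffer is two
    Lorentzians (jump-diffusion narrow width plus constant rotational
    width); the sample is the composite protein model — elastic amplitude
    from the sphere-confinement EISF, narrow width from the protein
    jump-diffusion law, broad width 2 D_R — with a buffer admixture, all
    convolved with the resolution, Debye–Waller damped, on a linear
    background, with Poisson counting noise.
    """
    omega = instrument.omega_grid
    step = instrument.omega_step
    q_grid = instrument.q_grid
    res = instrument.resolution_density(omega)
    delta = impulse_density(omega)

    broad_sample = rotational_hwhm(truth.sample_rot, 1)  # 2 D_R
    largest = max(broad_sample, truth.buffer_rot_width)
    if (instrument.omega_range[1] - instrument.omega_range[0]) < 10.0 * largest:
        import warnings

        warnings.warn(
            "omega range narrower than 10x the largest Lorentzian width; "
            "truncation will bias integrated intensities",
            stacklevel=2,
        )

    rng = np.random.default_rng(truth.seed)
    noise = truth.peak_counts is not None
    nq, nw = q_grid.size, omega.size

    protein_clean = np.empty((nq, nw))
    buffer_clean = np.empty((nq, nw))
    for iq, q in enumerate(q_grid):
        # protein composite: EISF-weighted elastic + two Lorentzians
        a0 = float(eisf_with_immobile(truth.sample_rot, q))
        g_nar = float(jump_diffusion_hwhm(truth.sample_jd, q))
        qel = 1.0 - a0
        model = CompositeSpectrumModel(
            dw=DebyeWallerFactor(truth.u2),
            elastic_amplitude=a0,
            lorentzians=(
                LorentzianComponent(hwhm=max(g_nar, 1e-6), amplitude=qel * truth.narrow_fraction),
                LorentzianComponent(hwhm=broad_sample, amplitude=qel * (1.0 - truth.narrow_fraction)),
            ),
            q=q,
        )
        # background is detector/cell noise, not scattering: added after the
        # resolution convolution, matching how the fits model it
        protein_clean[iq] = (
            convolve_resolution(evaluate_composite(model, omega, delta), res, step)
            + truth.bg_intercept
            + truth.bg_slope * omega
        )
        # buffer: narrow jump-diffusion + broad rotational Lorentzian
        g_buf = float(jump_diffusion_hwhm(truth.buffer_jd, q))
        buf = CompositeSpectrumModel(
            dw=DebyeWallerFactor(0.0),
            elastic_amplitude=0.0,
            lorentzians=(
                LorentzianComponent(hwhm=max(g_buf, 1e-6), amplitude=1.0),
                LorentzianComponent(hwhm=truth.buffer_rot_width, amplitude=truth.buffer_ratio),
            ),
            q=q,
        )
        buffer_clean[iq] = convolve_resolution(evaluate_composite(buf, omega, delta), res, step)

    # one global admixture scalar: after detector-efficiency normalization
    # the solvent contributes the same volume fraction at every Q, so its
    # coefficient in the sample must be Q-independent
    prot_int = np.trapezoid(protein_clean, omega, axis=1)
    buf_int = np.trapezoid(buffer_clean, omega, axis=1)
    buf_in_sample = buffer_clean * (
        truth.buffer_in_sample * prot_int.sum() / max(buf_int.sum(), 1e-30)
    )
    empty_clean = np.full((nq, nw), truth.empty_level * protein_clean.max())
    sample_clean = protein_clean + buf_in_sample + empty_clean
    # the neat buffer cell holds more solvent than the sample (the protein
    # displaces solvent_fill⁻¹ of it)
    buffer_meas = buf_in_sample / truth.solvent_fill + empty_clean
    vanadium_clean = np.tile(res, (nq, 1))

    # each measurement is counted to comparable statistics at its own peak,
    # as beam time would be allocated in practice; the applied scale factor
    # is recorded as the monitor so absolute intensities stay comparable
    peak = truth.peak_counts or 1e4
    spectra = {}
    for role, clean, sc in (
        ("sample", sample_clean, peak / sample_clean.max()),
        ("buffer", buffer_meas, peak / buffer_meas.max()),
        ("empty", empty_clean, peak / sample_clean.max()),
        ("vanadium", vanadium_clean, peak / vanadium_clean.max()),
    ):
        counts, errors = _apply_counting(clean, sc, rng, noise)
        spectra[role] = QENSSpectra(
            role=role,
            q_list=q_grid.copy(),
            omega_grid=omega.copy(),
            counts=counts,
            errors=errors,
            concentration=truth.concentration,
            temperature=310.0,
            monitor=sc,
        )
    return spectra


# ---------------------------------------------------------------------------
# Elastic scans
# ---------------------------------------------------------------------------

def gen_elastic_scan(
    u2_intercept: float,
    u2_slope: float,
    instrument: InstrumentProfile,
    noise_frac: float = 0.02,
    t_grid: np.ndarray | None = None,
    s0: float = 1.0,
    seed: int = 0,
    concentration: float = 0.0,
) -> ElasticScan:
    """Elastic scan with a linear MSD law u²(T) = intercept + slope·T.

    S_el(Q, T) = S₀ exp(-Q² u²(T)/3) with multiplicative Gaussian noise of
    fractional width ``noise_frac``.
    """
    if t_grid is None:
        t_grid = np.arange(270.0, 311.0, 5.0)
    t_grid = np.asarray(t_grid, dtype=float)
    u2 = u2_intercept + u2_slope * t_grid
    if np.any(u2 < 0):
        raise ValueError("u2(T) must be non-negative over the temperature grid")
    q = instrument.q_grid
    clean = s0 * np.exp(-np.outer(q**2, u2) / 3.0)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + noise_frac * rng.standard_normal(clean.shape)) if noise_frac else clean
    noisy = np.clip(noisy, 1e-12, None)
    errors = np.maximum(noise_frac * clean, 1e-12)
    return ElasticScan(
        q_grid=q.copy(),
        t_grid=t_grid,
        intensities=noisy,
        errors=errors,
        concentration=concentration,
        instrument_label=instrument.label,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(
    kind: str,
    n_atoms: int,
    n_frames: int,
    dt: float,
    D: float = 0.1,
    R: float = 3.0,
    tau0: float = 5.0,
    bout: float = 1.0,
    seed: int = 0,
) -> Trajectory:
    """Random-walk trajectories with known diffusion laws.

    ``free``: independent Gaussian steps with variance 2·D·dt per axis.
    ``confined_sphere``: the same walk with steps leaving a sphere of radius
    R rejected (redrawn), giving an MSD plateau at 2·(3R²/5) = 1.2 R².
    ``jump``: alternating exponential waiting times (mean ``tau0``, atom at
    rest) and diffusive bouts of mean duration ``bout`` with coefficient D.
    """
    rng = np.random.default_rng(seed)
    if kind == "free":
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, n_atoms, 3))
        coords = np.concatenate(
            [np.zeros((1, n_atoms, 3)), np.cumsum(steps, axis=0)], axis=0
        )
    elif kind == "confined_sphere":
        # reflecting wall: fold radial excursions back inside; unlike
        # rejection-resampling this preserves the uniform stationary
        # density, whose variance sets the MSD plateau 2·(3R²/5) = 1.2 R²
        coords = np.empty((n_frames, n_atoms, 3))
        pos = np.zeros((n_atoms, 3))
        coords[0] = pos
        sd = np.sqrt(2.0 * D * dt)
        for t in range(1, n_frames):
            pos = pos + rng.normal(0.0, sd, size=(n_atoms, 3))
            radius = np.linalg.norm(pos, axis=1)
            out = radius > R
            if np.any(out):
                pos[out] *= ((2.0 * R - radius[out]) / radius[out])[:, None]
            coords[t] = pos
    elif kind == "jump":
        # per-atom alternating rest/diffuse state with exponential durations
        coords = np.empty((n_frames, n_atoms, 3))
        pos = np.zeros((n_atoms, 3))
        coords[0] = pos
        sd = np.sqrt(2.0 * D * dt)
        moving = np.zeros(n_atoms, dtype=bool)
        remaining = rng.exponential(tau0, size=n_atoms)
        for t in range(1, n_frames):
            step = np.where(moving[:, None], rng.normal(0.0, sd, size=(n_atoms, 3)), 0.0)
            pos = pos + step
            coords[t] = pos
            remaining -= dt
            expired = remaining <= 0
            if np.any(expired):
                moving[expired] = ~moving[expired]
                draw = np.where(moving[expired], bout, tau0)
                remaining[expired] = rng.exponential(draw)
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")

    labels = [("C", i, "CA") for i in range(n_atoms)]
    return Trajectory(coords=coords, dt=dt, atom_labels=labels)


# ---------------------------------------------------------------------------
# Hydrogen-bond toy structures
# ---------------------------------------------------------------------------

def gen_hbond_toy(
    k_bonds: int, m_decoys: int, seed: int = 0, d_max: float = 3.2, angle_max: float = 40.0
) -> tuple[np.ndarray, dict, int]:
    """Plant donor–H–acceptor triples inside and outside the H-bond criteria.

    Returns (coords, flags, k_bonds): ``k_bonds`` triples satisfy both the
    distance and angle cutoffs; ``m_decoys`` violate at least one.  Triples
    sit on a 12 Å grid so no cross-triple pair can qualify.  ``flags`` holds
    boolean masks ``donor``/``hydrogen``/``acceptor`` and the integer map
    ``h_of_donor``.
    """
    rng = np.random.default_rng(seed)
    n = k_bonds + m_decoys
    coords = []
    donor, hydro, accep = [], [], []
    h_of_donor = {}
    side = max(int(np.ceil(n ** (1.0 / 3.0))), 1)
    offsets = [
        12.0 * np.array([i, j, k], dtype=float)
        for i in range(side)
        for j in range(side)
        for k in range(side)
    ][:n]

    for idx, origin in enumerate(offsets):
        is_bond = idx < k_bonds
        if is_bond:
            dist = rng.uniform(2.6, min(d_max, 3.1))
            dev = np.radians(rng.uniform(0.0, angle_max * 0.8))
        elif rng.random() < 0.5:
            dist = rng.uniform(d_max + 0.3, d_max + 2.0)  # fails distance
            dev = np.radians(rng.uniform(0.0, angle_max * 0.8))
        else:
            dist = rng.uniform(2.6, min(d_max, 3.1))
            dev = np.radians(rng.uniform(angle_max + 10.0, 85.0))  # fails angle

        # build the triple around the hydrogen: D 1.0 Å from H, the D-H...A
        # angle exactly 180° - dev, and |D-A| = dist; solve for the H-A
        # separation from the law of cosines, then rotate randomly
        r_ha = -np.cos(dev) + np.sqrt(max(dist**2 - np.sin(dev) ** 2, 0.0))
        local_d = np.array([-1.0, 0.0, 0.0])
        local_a = r_ha * np.array([np.cos(dev), np.sin(dev), 0.0])
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        perp = np.cross(axis, rng.standard_normal(3))
        perp /= np.linalg.norm(perp)
        third = np.cross(axis, perp)
        rot = np.stack([axis, perp, third], axis=1)  # orthonormal frame
        h_pos = origin
        d_pos = origin + rot @ local_d
        a_pos = origin + rot @ local_a

        base = len(coords)
        coords.extend([d_pos, h_pos, a_pos])
        donor.extend([True, False, False])
        hydro.extend([False, True, False])
        accep.extend([False, False, True])
        h_of_donor[base] = base + 1

    coords = np.asarray(coords, dtype=float)
    flags = {
        "donor": np.asarray(donor),
        "hydrogen": np.asarray(hydro),
        "acceptor": np.asarray(accep),
        "h_of_donor": h_of_donor,
    }
    return coords, flags, k_bonds
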