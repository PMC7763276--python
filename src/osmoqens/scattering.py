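"""Closed-form incoherent scattering laws and spectral building blocks.

The quasi-elastic spectrum of a hydrogen-rich sample is modelled as a
Debye–Waller-damped sum of an elastic line and Lorentzian quasi-elastic
components on a linear background,

    S(Q, ω) = exp(-⟨u²⟩Q²/3) [A₀(Q) δ(ω) + Σᵢ Aᵢ(Q) L(Γᵢ, ω)] + b₀ + b₁ ω,

convolved with the instrument resolution.  The Lorentzian half-widths carry
the dynamics: translational jump diffusion gives Γ(Q) = ħ D_T Q² / (1 + D_T
Q² τ₀), saturating at ħ/τ₀; rotational diffusion confined to a sphere gives
Q-independent widths Γ_l = ħ-scaled D_R l(l+1) and the Volino–Dianoux
elastic incoherent structure factor A₀(QR) = [3 j₁(QR)/QR]², optionally
mixed with an immobile fraction p.

All functions are vectorized over ω and Q.  Units follow
:mod:`osmoqens.constants`: meV, Å, ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import spherical_jn

from .constants import HBAR_MEV_PS

__all__ = [
    "JumpDiffusionParams",
    "ConfinedRotationParams",
    "DebyeWallerFactor",
    "LorentzianComponent",
    "CompositeSpectrumModel",
    "lorentzian_density",
    "jump_diffusion_hwhm",
    "brownian_hwhm",
    "sphere_eisf",
    "eisf_with_immobile",
    "rotational_hwhm",
    "evaluate_composite",
    "convolve_resolution",
    "impulse_density",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JumpDiffusionParams:
    """Translational jump-diffusion parameters.

    Attributes
    ----------
    D_T : float
        Translational diffusion coefficient, Å²/ps.
    tau0 : float
        Mean residence time between diffusive bouts, ps.  ``tau0 = 0``
        recovers free Brownian diffusion.
    """

    D_T: float
    tau0: float = 0.0

    def __post_init__(self) -> None:
        if self.D_T <= 0:
            raise ValueError(f"D_T must be positive, got {self.D_T}")
        if self.tau0 < 0:
            raise ValueError(f"tau0 must be non-negative, got {self.tau0}")


@dataclass(frozen=True)
class ConfinedRotationParams:
    """Rotational diffusion confined to a sphere, with an immobile fraction.

    Attributes
    ----------
    p : float
        Fraction of scatterers whose motion is unresolved within the
        instrumental time window (appears as extra elastic intensity).
    R : float
        Radius of the confining sphere, Å.
    D_R : float
        Rotational rate constant expressed in energy units, meV; the l-th
        multipole Lorentzian has half-width D_R·l(l+1).
    """

    p: float
    R: float
    D_R: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"immobile fraction p must lie in [0, 1], got {self.p}")
        if self.R <= 0:
            raise ValueError(f"sphere radius R must be positive, got {self.R}")
        if self.D_R < 0:
            raise ValueError(f"D_R must be non-negative, got {self.D_R}")


@dataclass(frozen=True)
class DebyeWallerFactor:
    """Thermal-displacement damping exp(-⟨u²⟩Q²/3); ``u2`` in Å²."""

    u2: float

    def __post_init__(self) -> None:
        if self.u2 < 0:
            raise ValueError(f"mean square displacement must be >= 0, got {self.u2}")

    def __call__(self, q: float) -> float:
        return float(np.exp(-self.u2 * q * q / 3.0))


@dataclass(frozen=True)
class LorentzianComponent:
    """One quasi-elastic Lorentzian: half-width ``hwhm`` (meV), weight ``amplitude``."""

    hwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.hwhm <= 0:
            raise ValueError(f"hwhm must be positive, got {self.hwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")


@dataclass(frozen=True)
class CompositeSpectrumModel:
    """Elastic line + Lorentzians + linear background at one Q."""

    dw: DebyeWallerFactor
    elastic_amplitude: float
    lorentzians: tuple[LorentzianComponent, ...] = field(default_factory=tuple)
    bg_slope: float = 0.0
    bg_intercept: float = 0.0
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.elastic_amplitude < 0:
            raise ValueError("elastic_amplitude must be non-negative")
        object.__setattr__(self, "lorentzians", tuple(self.lorentzians))


# ---------------------------------------------------------------------------
# Lineshapes and widths
# ---------------------------------------------------------------------------

def lorentzian_density(omega, hwhm: float):
    """Unit-normalized Lorentzian L(Γ, ω) = (1/π) Γ / (ω² + Γ²), 1/meV."""
    if hwhm <= 0:
        raise ValueError(f"Lorentzian hwhm must be positive, got {hwhm}")
    omega = np.asarray(omega, dtype=float)
    return (hwhm / np.pi) / (omega * omega + hwhm * hwhm)


def jump_diffusion_hwhm(params: JumpDiffusionParams, q):
    """Jump-diffusion half-width Γ(Q) = ħ D_T Q² / (1 + D_T Q² τ₀), meV.

    Rises linearly as ħ D_T Q² at small Q and saturates at ħ/τ₀.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Q must be non-negative")
    dq2 = params.D_T * q * q
    return HBAR_MEV_PS * dq2 / (1.0 + dq2 * params.tau0)


def brownian_hwhm(d_t: float, q):
    """Free-diffusion half-width Γ(Q) = ħ D_T Q², meV."""
    return jump_diffusion_hwhm(JumpDiffusionParams(D_T=d_t, tau0=0.0), q)


def sphere_eisf(r: float, q):
    """Elastic fraction for diffusion in a sphere, [3 j₁(QR)/QR]².

    Evaluates the analytic small-argument limit (→ 1) at QR = 0.
    """
    if r <= 0:
        raise ValueError(f"sphere radius must be positive, got {r}")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Q must be non-negative")
    x = q * r
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.ones_like(x)
    # 3j₁(x)/x = 1 - x²/10 + O(x⁴): below 1e-8 the limit is exact to
    # double precision and the direct ratio underflows
    nz = x > 1e-8
    out[nz] = (3.0 * spherical_jn(1, x[nz]) / x[nz]) ** 2
    return float(out[0]) if scalar else out


def eisf_with_immobile(params: ConfinedRotationParams, q):
    """EISF with immobile fraction: p + (1 - p)[3 j₁(QR)/QR]²."""
    return params.p + (1.0 - params.p) * sphere_eisf(params.R, q)


def rotational_hwhm(params: ConfinedRotationParams, l: int = 1) -> float:
    """Half-width of the l-th rotational multipole, Γ_l = D_R l(l+1), meV.

    The single-Lorentzian approximation used for broad quasi-elastic
    components keeps only l = 1, i.e. Γ = 2 D_R.
    """
    if not isinstance(l, (int, np.integer)) or l < 1:
        raise ValueError(f"multipole index l must be an integer >= 1, got {l}")
    return params.D_R * l * (l + 1)


# ---------------------------------------------------------------------------
# Grid-based spectrum assembly
# ---------------------------------------------------------------------------

def _check_uniform(omega_grid: np.ndarray) -> float:
    omega_grid = np.asarray(omega_grid, dtype=float)
    if omega_grid.ndim != 1 or omega_grid.size < 2:
        raise ValueError("omega grid must be a 1-D array with >= 2 points")
    steps = np.diff(omega_grid)
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-8, atol=1e-12 * abs(step)):
        raise ValueError("omega grid must be uniform")
    return float(step)


def impulse_density(omega_grid) -> np.ndarray:
    """Discrete delta: unit-integral impulse at the grid point closest to ω = 0."""
    omega_grid = np.asarray(omega_grid, dtype=float)
    step = _check_uniform(omega_grid)
    out = np.zeros_like(omega_grid)
    out[int(np.argmin(np.abs(omega_grid)))] = 1.0 / step
    return out


def evaluate_composite(model: CompositeSpectrumModel, omega_grid, elastic_shape) -> np.ndarray:
    """Evaluate the composite spectrum on a uniform ω grid.

    ``elastic_shape`` is the unit-normalized density standing in for the
    elastic delta function — in practice the measured resolution lineshape,
    or a discrete impulse when the result will be convolved afterwards.
    """
    omega_grid = np.asarray(omega_grid, dtype=float)
    _check_uniform(omega_grid)
    elastic_shape = np.asarray(elastic_shape, dtype=float)
    if elastic_shape.shape != omega_grid.shape:
        raise ValueError("elastic_shape must match the omega grid")
    qel = np.zeros_like(omega_grid)
    for comp in model.lorentzians:
        qel += comp.amplitude * lorentzian_density(omega_grid, comp.hwhm)
    dw = model.dw(model.q)
    background = model.bg_intercept + model.bg_slope * omega_grid
    return dw * (model.elastic_amplitude * elastic_shape + qel) + background


def convolve_resolution(model_values, resolution_values, omega_step: float) -> np.ndarray:
    """Convolve a model spectrum with a unit-normalized resolution density.

    Discrete linear convolution on the common uniform grid, truncated to the
    data support (same-length output).  With the resolution centred on the
    grid and normalized to unit integral, the total intensity is preserved up
    to truncation of the tails.
    """
    model_values = np.asarray(model_values, dtype=float)
    resolution_values = np.asarray(resolution_values, dtype=float)
    if model_values.shape != resolution_values.shape:
        raise ValueError("model and resolution must share one grid")
    if omega_step <= 0:
        raise ValueError("omega_step must be positive")
    return fftconvolve(model_values, resolution_values, mode="same") * omega_step
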