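"""Elastic-scan reduction: summed intensities and Gaussian-approximation MSD.

Within the Gaussian approximation the elastic incoherent intensity follows
S_el(Q) ≈ S₀ exp(-⟨u²⟩Q²/3), so the mean-square displacement at a given
temperature is -3× the slope of ln S_el against Q².  The approximation is
trusted only up to ⟨u²⟩Q² ≈ 1, which motivates the two-pass fitting window
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElasticScan", "MsdResult", "sum_intensities", "fit_msd"]


@dataclass
class ElasticScan:
    """Elastic intensity table S_el(Q, T) with uncertainties.

    ``intensities`` and ``errors`` are (n_Q, n_T) matrices aligned with the
    strictly increasing ``q_grid`` (Å⁻¹) and ``t_grid`` (K).
    """

    q_grid: np.ndarray
    t_grid: np.ndarray
    intensities: np.ndarray
    errors: np.ndarray
    concentration: float = 0.0
    instrument_label: str = ""

    def __post_init__(self) -> None:
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.q_grid.ndim != 1 or self.t_grid.ndim != 1:
            raise ValueError("q_grid and t_grid must be 1-D")
        if np.any(np.diff(self.q_grid) <= 0) or (
            self.t_grid.size > 1 and np.any(np.diff(self.t_grid) <= 0)
        ):
            raise ValueError("q_grid and t_grid must be strictly increasing")
        expected = (self.q_grid.size, self.t_grid.size)
        if self.intensities.shape != expected or self.errors.shape != expected:
            raise ValueError(
                f"intensity/error matrices must have shape {expected}, "
                f"got {self.intensities.shape} and {self.errors.shape}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("elastic intensities must be non-negative")


@dataclass
class MsdResult:
    """Mean-square displacement from one temperature slice.

    ``q2_window`` is the (min, max) of Q² actually used after windowing and
    ``n_points`` how many Q points entered the final fit.  ``window_fallback``
    is set when the validity mask would have left fewer than three points and
    the lowest-Q points were kept instead.
    """

    u2: float
    u2_error: float
    q2_window: tuple[float, float]
    n_points: int
    temperature: float = float("nan")
    window_fallback: bool = False


def sum_intensities(scan: ElasticScan) -> tuple[np.ndarray, np.ndarray]:
    """Sum S_el over all Q at each temperature.

    Returns (sums, errors), one entry per temperature; the error is the
    root-sum-square of the per-Q uncertainties.
    """
    if scan.q_grid.size == 0:
        raise ValueError("elastic scan has an empty Q grid")
    sums = scan.intensities.sum(axis=0)
    errs = np.sqrt((scan.errors**2).sum(axis=0))
    return sums, errs


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least-squares line fit; returns (slope, slope_se, intercept)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate Q² spread in MSD fit")
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    dof = max(x.size - 2, 1)
    # scale the formal variance by reduced chi^2 so the error is meaningful
    # for both statistical weights and unit weights
    chi2red = (w * resid**2).sum() / dof
    slope_se = np.sqrt(max(chi2red, np.finfo(float).tiny) / sxx)
    return float(slope), float(slope_se), float(intercept)


def fit_msd(scan: ElasticScan, temperature: float, max_u2q2: float = 1.0) -> MsdResult:
    """Extract ⟨u²⟩ at one temperature from the slope of ln S_el vs Q².

    A weighted linear regression (weights 1/σ² of ln S_el) is run twice: once
    on all usable points, then again after dropping points where the
    first-pass u² puts ⟨u²⟩Q² above ``max_u2q2``, the range beyond which the
    Gaussian approximation degrades.  If the mask would leave fewer than
    three points, the three lowest-Q usable points are kept instead.
    """
    it = int(np.argmin(np.abs(scan.t_grid - temperature)))
    if abs(scan.t_grid[it] - temperature) > 1e-6 + 1e-3 * abs(temperature):
        raise ValueError(f"temperature {temperature} K not present in scan")
    s = scan.intensities[:, it]
    sig = scan.errors[:, it]
    usable = s > 0
    if np.count_nonzero(~usable):
        warnings.warn(
            f"excluding {np.count_nonzero(~usable)} non-positive intensities "
            f"from the MSD fit at T={temperature} K",
            stacklevel=2,
        )
    if np.count_nonzero(usable) < 3:
        raise ValueError("fewer than 3 usable Q points for MSD fit")

    q2 = scan.q_grid[usable] ** 2
    y = np.log(s[usable])
    sig_y = np.where(sig[usable] > 0, sig[usable] / s[usable], np.nan)
    # unit weights for points with no stated uncertainty
    w = np.where(np.isfinite(sig_y) & (sig_y > 0), 1.0 / np.where(sig_y > 0, sig_y, 1.0) ** 2, 1.0)

    slope, _, _ = _wls_line(q2, y, w)
    u2_first = -3.0 * slope

    keep = u2_first * q2 <= max_u2q2 if u2_first > 0 else np.ones_like(q2, dtype=bool)
    fallback = False
    if np.count_nonzero(keep) < 3:
        keep = np.zeros_like(keep)
        keep[np.argsort(q2)[:3]] = True
        fallback = True

    slope, slope_se, _ = _wls_line(q2[keep], y[keep], w[keep])
    return MsdResult(
        u2=-3.0 * slope,
        u2_error=3.0 * slope_se,
        q2_window=(float(q2[keep].min()), float(q2[keep].max())),
        n_points=int(np.count_nonzero(keep)),
        temperature=float(scan.t_grid[it]),
        window_fallback=fallback,
    )
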