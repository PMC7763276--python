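"""Trajectory- and structure-level observables.

Estimators for molecular-dynamics validation of the scattering analysis:
lag-time mean-square displacement (the time-domain counterpart of the
Debye–Waller MSD), per-residue RMSF, and geometric hydrogen-bond and
atom–atom contact counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Trajectory",
    "HBondCriteria",
    "msd_lag",
    "rmsf_per_residue",
    "count_hbonds",
    "count_contacts",
]


@dataclass
class Trajectory:
    """Frame series: ``coords`` is (n_frames, n_atoms, 3) in Å, ``dt`` in ps.

    ``atom_labels`` holds (element, residue index, atom name) per atom;
    optional per-atom boolean ``flags`` (donor/hydrogen/acceptor) feed the
    hydrogen-bond counter.
    """

    coords: np.ndarray
    dt: float
    atom_labels: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([lbl[1] for lbl in self.atom_labels])


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    A donor D (with covalent hydrogen H) and acceptor A are bonded when the
    D–A distance is at most ``d_max`` and the D–H⋯A angle deviates from
    linearity (180°) by at most ``angle_max``.
    """

    d_max: float = 3.2
    angle_max: float = 40.0

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0.0 < self.angle_max < 90.0:
            raise ValueError("angle_max must lie in (0, 90) degrees")


def msd_lag(traj: Trajectory, tau: float, selection: np.ndarray | None = None) -> float:
    """Mean-square displacement at lag ``tau`` (ps), averaged over all
    overlapping time origins and selected atoms, in Å²."""
    k = tau / traj.dt
    k_int = int(round(k))
    if abs(k - k_int) > 1e-6 or k_int < 1:
        raise ValueError(f"tau={tau} ps is not a positive multiple of dt={traj.dt} ps")
    if k_int >= traj.n_frames:
        raise ValueError("tau exceeds the trajectory span")
    coords = traj.coords if selection is None else traj.coords[:, selection, :]
    disp = coords[k_int:] - coords[:-k_int]
    return float(np.mean(np.sum(disp**2, axis=-1)))


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``ref`` (both centred copies)."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return mc @ rot.T + ref.mean(axis=0)


def rmsf_per_residue(traj: Trajectory, superpose: bool = True) -> dict:
    """Root-mean-square fluctuation about the time-mean position, per residue.

    Frames are first least-squares superposed onto the mean structure
    (iterated once) so that rigid-body translation/rotation does not count
    as fluctuation.  Atomic RMSF values are averaged within each residue.
    """
    if traj.n_frames < 10:
        raise ValueError("RMSF needs at least 10 frames")
    coords = traj.coords
    if superpose:
        ref = coords.mean(axis=0)
        for _ in range(2):
            coords = np.stack([_kabsch(frame, ref) for frame in coords])
            ref = coords.mean(axis=0)
    mean_pos = coords.mean(axis=0)
    atomic = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=-1), axis=0))
    resids = traj.residue_ids
    return {int(r): float(atomic[resids == r].mean()) for r in np.unique(resids)}


def count_hbonds(
    coords: np.ndarray, flags: dict, criteria: HBondCriteria = HBondCriteria()
) -> int:
    """Count donor–acceptor pairs meeting the geometric hydrogen-bond criteria.

    ``flags`` must provide boolean masks ``donor``, ``hydrogen`` and
    ``acceptor``; an explicit ``h_of_donor`` map (donor index → hydrogen
    index) is used when present, otherwise each donor's hydrogen is the
    nearest flagged hydrogen within 1.25 Å (donors without one are skipped
    with a warning).
    """
    coords = np.asarray(coords, dtype=float)
    donors = np.flatnonzero(flags["donor"])
    acceptors = np.flatnonzero(flags["acceptor"])
    hydrogens = np.flatnonzero(flags["hydrogen"])
    h_map = flags.get("h_of_donor", {})
    if acceptors.size == 0 or donors.size == 0:
        return 0

    count = 0
    acc_pos = coords[acceptors]
    for d in donors:
        h = h_map.get(int(d))
        if h is None and hydrogens.size:
            dists = np.linalg.norm(coords[hydrogens] - coords[d], axis=1)
            j = int(np.argmin(dists))
            h = int(hydrogens[j]) if dists[j] <= 1.25 else None
        if h is None:
            warnings.warn(f"donor atom {d} has no covalent hydrogen; skipped", stacklevel=2)
            continue
        vec_da = acc_pos - coords[d]
        dist_da = np.linalg.norm(vec_da, axis=1)
        near = (dist_da <= criteria.d_max) & (acceptors != d) & (acceptors != h)
        if not np.any(near):
            continue
        hd = coords[d] - coords[h]
        ha = acc_pos[near] - coords[h]
        cosang = (ha @ hd) / (np.linalg.norm(ha, axis=1) * np.linalg.norm(hd) + 1e-30)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))  # ∠(D-H-A)
        count += int(np.count_nonzero(180.0 - angle <= criteria.angle_max))
    return count


def count_contacts(group_a: np.ndarray, group_b: np.ndarray, cutoff: float = 2.0) -> int:
    """Number of cross-group atom pairs within ``cutoff`` Å (neighbor-list)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.size == 0 or group_b.size == 0:
        return 0
    tree_a = cKDTree(group_a)
    tree_b = cKDTree(group_b)
    return int(tree_a.count_neighbors(tree_b, cutoff))
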