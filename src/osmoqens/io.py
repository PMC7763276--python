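"""Readers and writers for the package's text formats.

Elastic scans and per-Q spectra travel as tab-separated text with ``#``
header lines; an HDF5 container mirroring the same layout is accepted for
spectra.  Trajectory frame series (multi-model PDB, XYZ) are read through
MDAnalysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .elastic import ElasticScan
from .md import Trajectory
from .qens import QENSSpectra

__all__ = [
    "write_elastic_scan",
    "read_elastic_scan",
    "write_spectra",
    "read_spectra",
    "write_spectra_hdf5",
    "read_spectra_hdf5",
    "read_trajectory",
    "infer_hbond_flags",
]


# ---------------------------------------------------------------------------
# Elastic scans
# ---------------------------------------------------------------------------

def write_elastic_scan(scan: ElasticScan, path: str | Path) -> None:
    """Write a scan as TSV: Q column, then S/err column pairs per temperature."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# instrument\t{scan.instrument_label}\n")
        fh.write(f"# concentration_wt_pct\t{scan.concentration:g}\n")
        cols = ["Q_invA"]
        for t in scan.t_grid:
            cols += [f"S_{t:g}K", f"dS_{t:g}K"]
        fh.write("\t".join(cols) + "\n")
        for iq, q in enumerate(scan.q_grid):
            row = [f"{q:.6g}"]
            for it in range(scan.t_grid.size):
                row += [f"{scan.intensities[iq, it]:.8g}", f"{scan.errors[iq, it]:.8g}"]
            fh.write("\t".join(row) + "\n")


def read_elastic_scan(path: str | Path) -> ElasticScan:
    path = Path(path)
    instrument = ""
    concentration = 0.0
    header = None
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "instrument" and len(parts) > 1:
                instrument = parts[1]
            elif parts[0] == "concentration_wt_pct" and len(parts) > 1:
                concentration = float(parts[1])
            continue
        if header is None:
            header = line.split("\t")
        else:
            rows.append([float(v) for v in line.split("\t")])
    if header is None or not rows:
        raise ValueError(f"no tabular data in {path}")
    data = np.asarray(rows)
    t_grid = np.array([float(c[2:-1]) for c in header[1::2]])
    return ElasticScan(
        q_grid=data[:, 0],
        t_grid=t_grid,
        intensities=data[:, 1::2],
        errors=data[:, 2::2],
        concentration=concentration,
        instrument_label=instrument,
    )


# ---------------------------------------------------------------------------
# QENS spectra: TSV blocks per Q
# ---------------------------------------------------------------------------

def write_spectra(spectra: QENSSpectra, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# role\t{spectra.role}\n")
        fh.write(f"# concentration_wt_pct\t{spectra.concentration:g}\n")
        fh.write(f"# temperature_K\t{spectra.temperature:g}\n")
        fh.write(f"# monitor\t{spectra.monitor:.10g}\n")
        for iq, q in enumerate(spectra.q_list):
            fh.write(f"# Q = {q:.6g}\n")
            fh.write("omega_meV\tcounts\terror\n")
            for w, c, e in zip(spectra.omega_grid, spectra.counts[iq], spectra.errors[iq]):
                fh.write(f"{w:.6g}\t{c:.8g}\t{e:.8g}\n")


def read_spectra(path: str | Path) -> QENSSpectra:
    path = Path(path)
    role, conc, temp = "sample", 0.0, 310.0
    monitor = 1.0
    q_list: list[float] = []
    blocks: list[list[list[float]]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("Q ="):
                q_list.append(float(body.split("=", 1)[1]))
                blocks.append([])
            else:
                parts = body.split("\t")
                if parts[0] == "role" and len(parts) > 1:
                    role = parts[1]
                elif parts[0] == "concentration_wt_pct" and len(parts) > 1:
                    conc = float(parts[1])
                elif parts[0] == "temperature_K" and len(parts) > 1:
                    temp = float(parts[1])
                elif parts[0] == "monitor" and len(parts) > 1:
                    monitor = float(parts[1])
            continue
        if line.startswith("omega"):
            continue
        blocks[-1].append([float(v) for v in line.split("\t")])
    if not blocks:
        raise ValueError(f"no Q blocks in {path}")
    arr = np.asarray(blocks)  # (nQ, nω, 3)
    return QENSSpectra(
        role=role,
        q_list=np.asarray(q_list),
        omega_grid=arr[0, :, 0],
        counts=arr[:, :, 1],
        errors=arr[:, :, 2],
        concentration=conc,
        temperature=temp,
        monitor=monitor,
    )


def write_spectra_hdf5(spectra_by_role: dict[str, QENSSpectra], path: str | Path) -> None:
    """Write one or more spectra to an HDF5 container, one group per role."""
    import h5py

    with h5py.File(path, "w") as h5:
        for role, sp in spectra_by_role.items():
            grp = h5.create_group(role)
            grp.create_dataset("q_list", data=sp.q_list)
            grp.create_dataset("omega_grid", data=sp.omega_grid)
            grp.create_dataset("counts", data=sp.counts)
            grp.create_dataset("errors", data=sp.errors)
            grp.attrs["role"] = sp.role
            grp.attrs["concentration_wt_pct"] = sp.concentration
            grp.attrs["temperature_K"] = sp.temperature
            grp.attrs["monitor"] = sp.monitor


def read_spectra_hdf5(path: str | Path, role: str | None = None):
    """Read spectra from HDF5; returns one QENSSpectra or a dict of them."""
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        for key in h5:
            grp = h5[key]
            out[key] = QENSSpectra(
                role=str(grp.attrs.get("role", key)),
                q_list=grp["q_list"][...],
                omega_grid=grp["omega_grid"][...],
                counts=grp["counts"][...],
                errors=grp["errors"][...],
                concentration=float(grp.attrs.get("concentration_wt_pct", 0.0)),
                temperature=float(grp.attrs.get("temperature_K", 310.0)),
                monitor=float(grp.attrs.get("monitor", 1.0)),
            )
    if role is not None:
        return out[role]
    return out


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(path: str | Path, dt: float, flags_table: str | Path | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ frame series into a Trajectory.

    ``dt`` (ps) is the frame spacing, which neither format records
    reliably.  Donor/acceptor/hydrogen flags are inferred from element and
    atom name unless a sidecar table (TSV: index, donor, hydrogen,
    acceptor as 0/1) is supplied.
    """
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe(str(path))
    coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [mda.topology.guessers.guess_atom_element(n) for n in u.atoms.names]
    try:
        resids = [int(r) for r in u.atoms.resids]
    except Exception:
        resids = [0] * len(u.atoms)
    try:
        names = [str(n) for n in u.atoms.names]
    except Exception:
        names = elements
    labels = list(zip(elements, resids, names))
    traj = Trajectory(coords=coords, dt=dt, atom_labels=labels)
    if flags_table is not None:
        traj.flags = _read_flags_table(flags_table, traj.n_atoms)
    else:
        traj.flags = infer_hbond_flags(traj)
    return traj


def _read_flags_table(path: str | Path, n_atoms: int) -> dict:
    data = np.loadtxt(path, skiprows=1, dtype=int)
    flags = {
        "donor": np.zeros(n_atoms, dtype=bool),
        "hydrogen": np.zeros(n_atoms, dtype=bool),
        "acceptor": np.zeros(n_atoms, dtype=bool),
    }
    for row in np.atleast_2d(data):
        idx = int(row[0])
        flags["donor"][idx] = bool(row[1])
        flags["hydrogen"][idx] = bool(row[2])
        flags["acceptor"][idx] = bool(row[3])
    return flags


def infer_hbond_flags(traj: Trajectory, frame: int = 0) -> dict:
    """Heuristic flags: H atoms are hydrogens, N/O are acceptors, and N/O
    with a covalent hydrogen (within 1.25 Å in ``frame``) are donors."""
    elements = np.array([lbl[0].upper() for lbl in traj.atom_labels])
    hydrogen = elements == "H"
    polar = np.isin(elements, ["N", "O"])
    coords = traj.coords[frame]
    donor = np.zeros(traj.n_atoms, dtype=bool)
    h_of_donor = {}
    h_idx = np.flatnonzero(hydrogen)
    if h_idx.size:
        for i in np.flatnonzero(polar):
            d = np.linalg.norm(coords[h_idx] - coords[i], axis=1)
            j = int(np.argmin(d))
            if d[j] <= 1.25:
                donor[i] = True
                h_of_donor[int(i)] = int(h_idx[j])
    return {"donor": donor, "hydrogen": hydrogen, "acceptor": polar, "h_of_donor": h_of_donor}
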