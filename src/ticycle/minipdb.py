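"""Minimal PDB dialect used by the synthetic fixtures.

Standard ``ATOM`` records with one deliberate deviation: the occupancy
column (55-60) carries the atom's partial charge in elementary charges,
because the PDB format has no charge field.  Coordinates are written in
Angstrom on disk (PDB convention) and converted to nm in memory by the
reader.  Multi-frame trajectories are stored as multi-MODEL files.  This
dialect is produced and parsed only by this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["StructureFrame", "read_minipdb", "read_trajectory", "write_minipdb"]

_ANGSTROM_PER_NM = 10.0


@dataclass
class StructureFrame:
    """One frame of a structure: names, residues, charges, coordinates (nm)."""

    names: np.ndarray  # atom names, str
    residue_ids: np.ndarray  # int
    residue_names: np.ndarray  # str
    charges: np.ndarray  # partial charges, e; NaN when absent
    coords: np.ndarray  # (n_atoms, 3) nm
    c6: np.ndarray | None = None  # optional per-atom LJ sqrt-coefficients
    c12: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.names)
        if n < 1:
            raise ValueError("a frame needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atoms_of_residue(self, residue_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.residue_ids == residue_id)
        if len(idx) == 0:
            raise KeyError(f"no residue with id {residue_id}")
        return idx

    def with_coords(self, coords: np.ndarray) -> "StructureFrame":
        return StructureFrame(
            names=self.names,
            residue_ids=self.residue_ids,
            residue_names=self.residue_names,
            charges=self.charges,
            coords=np.asarray(coords, dtype=float),
            c6=self.c6,
            c12=self.c12,
        )


def _format_atom(serial, name, resname, resid, xyz_nm, charge):
    x, y, z = (c * _ANGSTROM_PER_NM for c in xyz_nm)
    q = 0.0 if charge is None or np.isnan(charge) else charge
    return (
        f"ATOM  {serial:>5d} {name:<4.4s} {resname:<3.3s} A{resid:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{q:6.2f}{0.0:6.2f}\n"
    )


def write_minipdb(frame_or_frames, path) -> None:
    """Write a StructureFrame (or a list of frames as MODELs) to disk."""
    frames = (
        [frame_or_frames]
        if isinstance(frame_or_frames, StructureFrame)
        else list(frame_or_frames)
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("REMARK   minimal PDB dialect: occupancy column = partial charge (e)\n")
        multi = len(frames) > 1
        for m, fr in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            for a in range(fr.n_atoms):
                fh.write(
                    _format_atom(
                        a + 1,
                        str(fr.names[a]),
                        str(fr.residue_names[a]),
                        int(fr.residue_ids[a]),
                        fr.coords[a],
                        float(fr.charges[a]),
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _parse_atom_line(line, lineno, path):
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        resid = int(line[22:26])
        x = float(line[30:38]) / _ANGSTROM_PER_NM
        y = float(line[38:46]) / _ANGSTROM_PER_NM
        z = float(line[46:54]) / _ANGSTROM_PER_NM
        occ = line[54:60].strip()
        charge = float(occ) if occ else np.nan
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed ATOM record") from exc
    return name, resname, resid, (x, y, z), charge


def read_trajectory(path) -> list[StructureFrame]:
    """Read all MODELs of a minimal-PDB file; a plain file yields one frame."""
    path = Path(path)
    frames: list[StructureFrame] = []
    names, resnames, resids, coords, charges = [], [], [], [], []

    def flush():
        nonlocal names, resnames, resids, coords, charges
        if names:
            frames.append(
                StructureFrame(
                    names=np.array(names),
                    residue_ids=np.array(resids, dtype=int),
                    residue_names=np.array(resnames),
                    charges=np.array(charges, dtype=float),
                    coords=np.array(coords, dtype=float),
                )
            )
        names, resnames, resids, coords, charges = [], [], [], [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "ATOM":
                name, resname, resid, xyz, q = _parse_atom_line(line, lineno, path)
                names.append(name)
                resnames.append(resname)
                resids.append(resid)
                coords.append(xyz)
                charges.append(q)
            elif rec == "ENDMDL":
                flush()
    flush()
    if not frames:
        raise ValueError(f"{path}: no ATOM records found")
    return frames


def read_minipdb(path) -> StructureFrame:
    """Read a single-frame minimal-PDB file."""
    return read_trajectory(path)[0]
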