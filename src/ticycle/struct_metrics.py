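"""Per-residue trajectory metrics for protein-interface analysis.

Implements the quantities used to compare native and modified interface
residues: RMSD after rotational-translational (Kabsch) fitting, per-residue
RMSF, residue-environment nonbonded interaction energy under reaction-field
electrostatics, geometric hydrogen-bond counts, and counts of oppositely
charged groups within distance cutoffs (0.3 and 0.6 nm by default).

Distances are plain Euclidean (fixtures are non-periodic); coordinates are
nm throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .minipdb import StructureFrame
from .units import F_COULOMB

__all__ = [
    "RfParams",
    "DonorAcceptorTable",
    "ChargeContactCounts",
    "CHARGED_GROUPS",
    "kabsch_superpose",
    "rmsf",
    "residue_interaction_energy",
    "rf_coulomb",
    "count_hbonds",
    "count_charge_contacts",
    "summarize_residue",
    "summarize_residues",
]


@dataclass(frozen=True)
class RfParams:
    """Reaction-field electrostatics constants.

    The pair potential f q_i q_j (1/r + k_rf r^2 - c_rf) vanishes
    continuously at the cutoff by construction of c_rf.
    """

    cutoff: float = 1.4  # nm
    eps_rf: float = 65.0
    k_rf: float = field(init=False)
    c_rf: float = field(init=False)

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.eps_rf < 1:
            raise ValueError("reaction-field dielectric must be >= 1")
        k_rf = (self.eps_rf - 1.0) / ((2.0 * self.eps_rf + 1.0) * self.cutoff**3)
        object.__setattr__(self, "k_rf", k_rf)
        object.__setattr__(self, "c_rf", 1.0 / self.cutoff + k_rf * self.cutoff**2)


def rf_coulomb(r, qi, qj, rf: RfParams):
    """Reaction-field Coulomb pair energy in kJ/mol (zero beyond cutoff)."""
    r = np.asarray(r, dtype=float)
    e = F_COULOMB * qi * qj * (1.0 / r + rf.k_rf * r**2 - rf.c_rf)
    return np.where(r <= rf.cutoff, e, 0.0)


def kabsch_superpose(
    reference: StructureFrame | np.ndarray,
    mobile: StructureFrame | np.ndarray,
    selection: np.ndarray | None = None,
    fit: bool = True,
):
    """Least-squares rigid superposition and post-fit RMSD (nm).

    Returns ``(rmsd, (rotation_matrix, translation))``.  With
    ``fit=False`` no transform is applied and the raw coordinate RMSD is
    returned (rotation = identity).  The fitted RMSD is invariant under
    any rigid pre-transformation of the mobile frame.
    """
    ref = reference.coords if isinstance(reference, StructureFrame) else np.asarray(reference)
    mob = mobile.coords if isinstance(mobile, StructureFrame) else np.asarray(mobile)
    if selection is not None:
        ref = ref[selection]
        mob = mob[selection]
    if ref.shape != mob.shape:
        raise ValueError(
            f"selection size mismatch: reference {ref.shape} vs mobile {mob.shape}"
        )
    n = len(ref)
    if not fit:
        rmsd = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
        return rmsd, (np.eye(3), np.zeros(3))
    if n < 3:
        raise ValueError("need at least 3 atoms for a rigid fit")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    rmat = rot.as_matrix()
    translation = ref.mean(axis=0) - rot.apply(mob.mean(axis=0))
    # recompute the residual directly: the rssd reported by align_vectors
    # suffers cancellation for near-exact superpositions
    fitted = mob @ rmat.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return rmsd, (rmat, translation)


def fit_trajectory(
    reference: StructureFrame, frames: Sequence[StructureFrame]
) -> list[StructureFrame]:
    """Kabsch-fit every frame onto the reference (all atoms)."""
    out = []
    for fr in frames:
        _, (rmat, t) = kabsch_superpose(reference, fr)
        out.append(fr.with_coords(fr.coords @ rmat.T + t))
    return out


def rmsf(
    frames: Sequence[StructureFrame], residue_id: int, structure: StructureFrame | None = None
) -> float:
    """Residue RMSF in nm: per-atom fluctuation about the time-mean
    position, averaged over the residue's atoms.

    Frames are assumed already fitted to a common reference.
    """
    if len(frames) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    template = structure if structure is not None else frames[0]
    idx = template.atoms_of_residue(residue_id)
    x = np.stack([fr.coords[idx] for fr in frames])  # (F, A, 3)
    mean_pos = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean_pos) ** 2, axis=2), axis=0))
    return float(np.mean(per_atom))


def residue_interaction_energy(
    frame: StructureFrame, residue_id: int, rf: RfParams = RfParams()
) -> float:
    """Nonbonded energy (kJ/mol) between one residue and its surroundings.

    Sum over pairs (residue atom, non-residue atom) within the cutoff of
    the LJ term c12/r^12 - c6/r^6 (when per-atom LJ parameters are
    present; combined geometrically) plus the reaction-field Coulomb term.
    """
    idx = frame.atoms_of_residue(residue_id)
    rest = np.setdiff1d(np.arange(frame.n_atoms), idx)
    if len(rest) == 0:
        return 0.0
    q = frame.charges
    if np.any(np.isnan(q[idx])) or np.any(np.isnan(q[rest])):
        raise ValueError(
            "missing partial charges: the minimal-PDB dialect stores charge "
            "in the occupancy column"
        )
    r = cdist(frame.coords[idx], frame.coords[rest])
    within = r <= rf.cutoff
    if np.any(r[within] == 0.0):
        raise ZeroDivisionError("coincident atoms in interaction energy")
    # excluded pairs get a dummy finite separation; their terms are masked out
    r_safe = np.where(within, r, rf.cutoff)
    e_coul = F_COULOMB * np.outer(q[idx], q[rest]) * (
        1.0 / r_safe + rf.k_rf * r_safe**2 - rf.c_rf
    )
    e = float(np.sum(np.where(within, e_coul, 0.0)))
    if frame.c6 is not None and frame.c12 is not None:
        c6 = np.sqrt(np.outer(frame.c6[idx], frame.c6[rest]))
        c12 = np.sqrt(np.outer(frame.c12[idx], frame.c12[rest]))
        e_lj = c12 / r_safe**12 - c6 / r_safe**6
        e += float(np.sum(np.where(within, e_lj, 0.0)))
    return e


@dataclass(frozen=True)
class DonorAcceptorTable:
    """Hydrogen-bond chemistry: donor and acceptor atom-name sets.

    When ``donors`` is None, every N*/O* atom with an attached hydrogen is
    treated as a donor; when ``acceptors`` is None, every N*/O* atom is an
    acceptor (the usual heavy-atom convention).
    """

    donors: frozenset | None = None
    acceptors: frozenset | None = None
    dist_cutoff: float = 0.35  # donor-acceptor, nm
    angle_cutoff: float = 30.0  # H-D-A deviation from linearity, deg
    dh_bond_max: float = 0.115  # covalent D-H search radius, nm


def _attached_hydrogens(frame: StructureFrame, donor_idx: int, table) -> np.ndarray:
    same_res = frame.residue_ids == frame.residue_ids[donor_idx]
    is_h = np.char.startswith(frame.names.astype(str), "H")
    cand = np.flatnonzero(same_res & is_h)
    if len(cand) == 0:
        return cand
    d = np.linalg.norm(frame.coords[cand] - frame.coords[donor_idx], axis=1)
    return cand[d <= table.dh_bond_max]


def count_hbonds(
    frame: StructureFrame,
    residue_id: int,
    table: DonorAcceptorTable = DonorAcceptorTable(),
) -> int:
    """Hydrogen bonds between one residue and the rest of the structure.

    Geometric criterion: donor-acceptor distance <= 0.35 nm and H-D-A
    angle <= 30 deg for at least one hydrogen attached to the donor.
    Donors listed explicitly in the table must carry a hydrogen.
    """
    names = frame.names.astype(str)
    heavy = np.array([n.startswith(("N", "O")) for n in names])
    if table.donors is not None:
        donor_mask = np.isin(names, list(table.donors))
    else:
        donor_mask = heavy.copy()
    if table.acceptors is not None:
        acceptor_mask = np.isin(names, list(table.acceptors))
    else:
        acceptor_mask = heavy
    donors = []
    for i in np.flatnonzero(donor_mask):
        hs = _attached_hydrogens(frame, i, table)
        if len(hs) == 0:
            if table.donors is not None:
                raise ValueError(
                    f"donor atom {names[i]} (residue {frame.residue_ids[i]}) "
                    "has no attached hydrogen"
                )
            continue
        donors.append((i, hs))

    in_res = frame.residue_ids == residue_id
    if not np.any(in_res):
        raise KeyError(f"no residue with id {residue_id}")
    count = 0
    for d_idx, hs in donors:
        for a_idx in np.flatnonzero(acceptor_mask):
            if in_res[d_idx] == in_res[a_idx]:
                continue  # count only residue <-> rest bonds
            if frame.residue_ids[d_idx] == frame.residue_ids[a_idx]:
                continue
            da = frame.coords[a_idx] - frame.coords[d_idx]
            dist = np.linalg.norm(da)
            if dist > table.dist_cutoff or dist == 0.0:
                continue
            for h_idx in hs:
                dh = frame.coords[h_idx] - frame.coords[d_idx]
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang <= table.angle_cutoff:
                    count += 1
                    break
    return count


#: Formal charges of side-chain charged groups by residue name; the group
#: is located by its member atom names.  Editable by passing a custom
#: mapping to count_charge_contacts.
CHARGED_GROUPS: dict[str, tuple[tuple[str, ...], int]] = {
    "LYS": (("NZ",), +1),
    "ARG": (("NH1", "NH2", "NE"), +1),
    "ASP": (("OD1", "OD2"), -1),
    "GLU": (("OE1", "OE2"), -1),
    "HIP": (("ND1", "NE2"), +1),  # doubly protonated histidine
    "OCS": (("OD1", "OD2", "OD3"), -1),  # cysteic acid sulfonate
}


@dataclass(frozen=True)
class ChargeContactCounts:
    """Cumulative opposite-charge contact counts per cutoff plus the
    annulus count between the two cutoffs."""

    counts: dict  # cutoff (nm) -> cumulative count
    annulus: int  # contacts with min-distance in (low, high]

    def __getitem__(self, cutoff: float) -> int:
        return self.counts[cutoff]


def _charged_groups(frame: StructureFrame, groups: dict):
    """(residue_id, formal_charge, atom indices) of every charged group."""
    found = []
    for rid in np.unique(frame.residue_ids):
        idx = np.flatnonzero(frame.residue_ids == rid)
        resname = str(frame.residue_names[idx[0]])
        if resname not in groups:
            continue
        member_names, charge = groups[resname]
        members = idx[np.isin(frame.names[idx].astype(str), list(member_names))]
        if len(members) > 0:
            found.append((int(rid), charge, members))
    return found


def count_charge_contacts(
    frame: StructureFrame,
    residue_id: int,
    cutoffs: Sequence[float] = (0.3, 0.6),
    groups: dict | None = None,
) -> ChargeContactCounts:
    """Oppositely charged groups near one residue's charged group.

    For each cutoff, the number of opposite-sign groups whose minimum
    interatomic distance to the residue's group is <= cutoff (cumulative,
    so count(0.3) <= count(0.6)); the annulus count between the smallest
    and largest cutoff is reported as well.  A residue without a charged
    group yields zero counts with a warning.
    """
    groups = CHARGED_GROUPS if groups is None else groups
    cutoffs = sorted(float(c) for c in cutoffs)
    all_groups = _charged_groups(frame, groups)
    mine = [g for g in all_groups if g[0] == residue_id]
    if not mine:
        warnings.warn(
            f"residue {residue_id} carries no charged group; counts are zero",
            stacklevel=2,
        )
        return ChargeContactCounts(counts={c: 0 for c in cutoffs}, annulus=0)
    _, my_charge, my_atoms = mine[0]
    min_dists = []
    for rid, charge, members in all_groups:
        if rid == residue_id or charge * my_charge >= 0:
            continue
        d = cdist(frame.coords[my_atoms], frame.coords[members]).min()
        min_dists.append(d)
    min_dists = np.array(min_dists)
    counts = {c: int(np.sum(min_dists <= c)) for c in cutoffs}
    annulus = int(np.sum((min_dists > cutoffs[0]) & (min_dists <= cutoffs[-1])))
    return ChargeContactCounts(counts=counts, annulus=annulus)


def summarize_residue(
    structure: StructureFrame,
    frames: Sequence[StructureFrame],
    residue_id: int,
    rf: RfParams = RfParams(),
    cutoffs: Sequence[float] = (0.3, 0.6),
    hbond_table: DonorAcceptorTable = DonorAcceptorTable(),
) -> dict:
    """All interface metrics for one residue, averaged over frames."""
    fitted = fit_trajectory(structure, frames)
    energies = [residue_interaction_energy(fr, residue_id, rf) for fr in fitted]
    hbonds = [count_hbonds(fr, residue_id, hbond_table) for fr in fitted]
    contacts = [count_charge_contacts(fr, residue_id, cutoffs) for fr in fitted]
    low, high = sorted(cutoffs)[0], sorted(cutoffs)[-1]
    return {
        "residue_id": residue_id,
        "rmsf_nm": rmsf(fitted, residue_id, structure),
        "interaction_energy_kj_mol": float(np.mean(energies)),
        "hbond_count": float(np.mean(hbonds)),
        f"contacts_within_{low}_nm": float(np.mean([c[low] for c in contacts])),
        f"contacts_within_{high}_nm": float(np.mean([c[high] for c in contacts])),
        "contacts_annulus": float(np.mean([c.annulus for c in contacts])),
    }


def summarize_residues(
    structure: StructureFrame,
    frames: Sequence[StructureFrame],
    residue_ids: Sequence[int],
    **kwargs,
) -> pd.DataFrame:
    """Interaction summary table over several residues."""
    rows = [summarize_residue(structure, frames, rid, **kwargs) for rid in residue_ids]
    return pd.DataFrame(rows).set_index("residue_id")
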