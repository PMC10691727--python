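"""Structure geometry: least-squares superposition with iterative outlier
pruning, van-der-Waals overlap contacts, and geometric hydrogen bonds.

These mirror the structure-viewer analyses used to compare the insect
models against the Dcytb crystal structure: a Kabsch fit with iterative
pruning of deviant atom pairs (reported as both a pruned and an all-pairs
RMSD), contacts defined by van-der-Waals overlap r_a + r_b − d against a
cutoff, and hydrogen bonds by a heavy-atom distance/angle criterion (no
hydrogen placement — crystallographic and predicted models carry none).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .seqio import Atom, StructureModel

__all__ = [
    "VDW_RADII",
    "VDW_TABLE_NAME",
    "SuperpositionResult",
    "ContactSet",
    "HBond",
    "kabsch",
    "prune_superpose",
    "vdw_contacts",
    "hbonds",
    "ligand_contact_table",
]

#: Bondi (1964) van der Waals radii in Å, extended with common metals.
VDW_TABLE_NAME = "bondi64-extended"
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "FE": 2.05, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "NA": 2.27, "K": 2.75,
    "MN": 2.05, "CU": 1.40, "NI": 1.63, "CO": 2.00,
}


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping the mobile point set onto the reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd_all: float
    rmsd_pruned: float
    n_all: int
    n_pruned: int
    retained: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if abs(float(np.linalg.det(self.rotation)) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        if self.n_pruned > self.n_all:
            raise ValueError("n_pruned cannot exceed n_all")
        if self.rmsd_pruned > self.rmsd_all + 1e-9:
            raise ValueError("pruned RMSD cannot exceed all-pairs RMSD")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _as_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        a, b = (np.asarray(p, dtype=float) for p in pairs)
    else:
        arr = np.asarray([(p[0], p[1]) for p in pairs], dtype=float)
        a, b = arr[:, 0, :], arr[:, 1, :]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("pairs must be two matching (n, 3) point sets")
    return a, b


def _fit(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation/translation mapping mob onto ref (Kabsch/SVD)."""
    cr, cm = ref.mean(axis=0), mob.mean(axis=0)
    h = (mob - cm).T @ (ref - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    return rot, trans


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch(pairs) -> SuperpositionResult:
    """Optimal rigid superposition of paired points (no pruning).

    ``pairs`` is either a (ref_points, mobile_points) tuple of (n, 3) arrays
    or an iterable of (ref_point, mobile_point) pairs. Needs at least 3
    non-coincident pairs.
    """
    ref, mob = _as_pairs(pairs)
    n = len(ref)
    if n < 3:
        raise ValueError(f"superposition needs >= 3 pairs, got {n}")
    if np.linalg.matrix_rank(ref - ref.mean(axis=0)) < 2:
        raise ValueError("degenerate geometry: reference points are collinear")
    rot, trans = _fit(ref, mob)
    moved = mob @ rot.T + trans
    rmsd = _rmsd(ref, moved)
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd_all=rmsd,
        rmsd_pruned=rmsd,
        n_all=n,
        n_pruned=n,
        retained=tuple(range(n)),
    )


def prune_superpose(
    pairs, prune_cutoff: float = 2.0, max_iter: int = 100
) -> SuperpositionResult:
    """Iteratively pruned superposition.

    Fit on the current pair set, drop pairs whose post-fit deviation exceeds
    ``prune_cutoff`` Å, refit; stop when stable, when ``max_iter`` is
    reached, or just before the retained set would fall below 3 pairs (then
    the last stable fit is reported with a warning). ``rmsd_pruned`` is over
    retained pairs and ``rmsd_all`` over all pairs, both under the final
    transform.
    """
    ref, mob = _as_pairs(pairs)
    n = len(ref)
    keep = np.arange(n)
    rot, trans = None, None
    for _ in range(max_iter):
        rot, trans = _fit(ref[keep], mob[keep])
        dev = np.linalg.norm(mob @ rot.T + trans - ref, axis=1)
        new_keep = np.flatnonzero(dev[keep] <= prune_cutoff)
        if len(new_keep) == len(keep):
            break
        if len(new_keep) < 3:
            warnings.warn(
                "pruning would retain fewer than 3 pairs; reporting last "
                "stable fit",
                stacklevel=2,
            )
            break
        keep = keep[new_keep]
    moved = mob @ rot.T + trans
    return SuperpositionResult(
        rotation=rot,
        translation=trans,
        rmsd_all=_rmsd(ref, moved),
        rmsd_pruned=_rmsd(ref[keep], moved[keep]),
        n_all=n,
        n_pruned=len(keep),
        retained=tuple(int(i) for i in keep),
    )


def _radius(atom: Atom) -> float:
    try:
        return VDW_RADII[atom.element.upper()]
    except KeyError:
        raise ValueError(
            f"no van der Waals radius for element {atom.element!r} "
            f"(atom {atom.atom_name} {atom.residue_name}{atom.residue_number})"
        ) from None


@dataclass(frozen=True)
class ContactSet:
    """Atom pairs in van-der-Waals contact between two selections."""

    pairs: tuple[tuple[Atom, Atom, float, float], ...]  # (a, b, distance, overlap)
    overlap_cutoff: float
    hbond_allowance: float
    radii_table: str = VDW_TABLE_NAME

    def __len__(self) -> int:
        return len(self.pairs)

    def residues_in_contact(self) -> set[tuple[str, int, str]]:
        return {a.residue_key for a, _, _, _ in self.pairs}


_POLAR = {"N", "O"}


def vdw_contacts(
    model: StructureModel,
    selection_a,
    selection_b,
    overlap_cutoff: float = -0.4,
    hbond_allowance: float = 0.0,
) -> ContactSet:
    """Van-der-Waals overlap contacts between two disjoint atom selections.

    A pair is reported when overlap = r_a + r_b − d ≥ overlap_cutoff, with
    ``hbond_allowance`` subtracted from the required overlap when both
    elements are N/O (potential donor/acceptor pairs). Pairs within one
    residue are never reported. Selections may be iterables of atoms or
    predicates over atoms.
    """
    atoms_a = _resolve_selection(model, selection_a)
    atoms_b = _resolve_selection(model, selection_b)
    if set(map(id, atoms_a)) & set(map(id, atoms_b)):
        raise ValueError("selections must be disjoint at the atom level")
    if not atoms_a or not atoms_b:
        return ContactSet((), overlap_cutoff, hbond_allowance)
    ra = np.array([_radius(a) for a in atoms_a])
    rb = np.array([_radius(b) for b in atoms_b])
    xa = np.array([a.xyz for a in atoms_a])
    xb = np.array([b.xyz for b in atoms_b])
    # largest distance that can still satisfy the loosest criterion
    reach = ra.max() + rb.max() - overlap_cutoff + max(hbond_allowance, 0.0)
    tree = cKDTree(xb)
    out = []
    for i, atom in enumerate(atoms_a):
        for j in tree.query_ball_point(xa[i], r=reach):
            b = atoms_b[j]
            if atom.residue_key == b.residue_key:
                continue
            d = float(np.linalg.norm(xa[i] - xb[j]))
            overlap = ra[i] + rb[j] - d
            required = overlap_cutoff
            if atom.element.upper() in _POLAR and b.element.upper() in _POLAR:
                required -= hbond_allowance
            if overlap >= required:
                out.append((atom, b, d, float(overlap)))
    out.sort(key=lambda p: (p[0].residue_number, p[0].atom_name, p[1].residue_number))
    return ContactSet(tuple(out), overlap_cutoff, hbond_allowance)


def _resolve_selection(model: StructureModel, selection) -> list[Atom]:
    if callable(selection):
        return [a for a in model.atoms if selection(a)]
    return list(selection)


@dataclass(frozen=True)
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float
    donor_angle: float | None  # None when the donor has no bonded antecedent


def hbonds(
    model: StructureModel,
    selection_a,
    selection_b,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    include_sulfur: bool = False,
) -> list[HBond]:
    """Geometric hydrogen bonds between two selections (heavy atoms only).

    Donor and acceptor are N/O (S optionally) heavy atoms; a bond requires
    donor–acceptor distance ≤ ``d_max`` and the angle
    antecedent–donor–acceptor ≥ ``angle_min`` for at least one covalently
    bonded antecedent (heavy atoms within 1.9 Å in the same residue). Donors
    without an antecedent pass the angle criterion vacuously. Both donor
    directions are evaluated, so the result is symmetric in the selections.
    """
    polar = _POLAR | ({"S"} if include_sulfur else set())
    atoms_a = [a for a in _resolve_selection(model, selection_a) if a.element.upper() in polar]
    atoms_b = [a for a in _resolve_selection(model, selection_b) if a.element.upper() in polar]
    by_residue: dict[tuple, list[Atom]] = {}
    for a in model.atoms:
        by_residue.setdefault(a.residue_key, []).append(a)

    def antecedents(atom: Atom) -> list[Atom]:
        out = []
        for other in by_residue[atom.residue_key]:
            if other is atom or other.element.upper() == "H":
                continue
            if math.dist(atom.xyz, other.xyz) <= 1.9:
                out.append(other)
        return out

    def angle(p1, p2, p3) -> float:
        v1 = np.asarray(p1) - np.asarray(p2)
        v2 = np.asarray(p3) - np.asarray(p2)
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    found: dict[tuple, HBond] = {}
    for donors, acceptors in ((atoms_a, atoms_b), (atoms_b, atoms_a)):
        for don in donors:
            for acc in acceptors:
                if don.residue_key == acc.residue_key:
                    continue
                d = math.dist(don.xyz, acc.xyz)
                if d > d_max:
                    continue
                ants = antecedents(don)
                if ants:
                    best = max(angle(a.xyz, don.xyz, acc.xyz) for a in ants)
                    if best < angle_min:
                        continue
                    ang = best
                else:
                    ang = None
                key = tuple(sorted([id(don), id(acc)]))
                if key not in found:
                    found[key] = HBond(donor=don, acceptor=acc, distance=d, donor_angle=ang)
    return sorted(
        found.values(),
        key=lambda h: (h.donor.residue_number, h.donor.atom_name, h.acceptor.residue_number),
    )


def ligand_contact_table(
    model: StructureModel,
    ligand_names: set[str] = frozenset({"HEM", "ASC"}),
    overlap_cutoff: float = -0.4,
    hbond_allowance: float = 0.0,
):
    """Per-residue contact counts against each named ligand.

    Returns a DataFrame indexed by (chain, residue number, residue name),
    one column per ligand, sorted by residue number; residues with at least
    one contact to any ligand are flagged. Absent ligands yield an empty
    column with a warning.
    """
    import pandas as pd

    protein = model.protein_atoms()
    columns = {}
    for name in sorted(ligand_names):
        lig_atoms = model.ligand_atoms([name])
        if not lig_atoms:
            warnings.warn(f"ligand {name!r} absent from structure", stacklevel=2)
            columns[name] = {}
            continue
        contacts = vdw_contacts(
            model, protein, lig_atoms, overlap_cutoff, hbond_allowance
        )
        counts: dict[tuple, int] = {}
        for a, _, _, _ in contacts.pairs:
            counts[a.residue_key] = counts.get(a.residue_key, 0) + 1
        columns[name] = counts
    residues = sorted(
        {a.residue_key for a in protein}, key=lambda k: (k[0], k[1])
    )
    df = pd.DataFrame(
        {
            name: [counts.get(r, 0) for r in residues]
            for name, counts in columns.items()
        },
        index=pd.MultiIndex.from_tuples(residues, names=["chain", "resnum", "resname"]),
    )
    df["any_contact"] = (df.sum(axis=1) > 0) if len(df.columns) else False
    return df
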