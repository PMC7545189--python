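"""Hydrogen bonds and salt bridges across a binary interface.

All criteria are heavy-atom based — the structures this targets (2.4-3.3 A
crystallography) carry no hydrogens, so the standard low-resolution practice
is used: a donor/acceptor pair counts as a hydrogen bond when the heavy-atom
distance is within ``d_max`` (default 3.5 A) and the angle at the donor
(antecedent-donor-acceptor, antecedent = a covalently bonded heavy atom of
the donor's residue) is at least ``angle_min`` (default 90 degrees).

Donor typing: any nitrogen except the proline backbone N; hydroxyl oxygens of
Ser/Thr/Tyr; saccharide hydroxyl oxygens (so glycan-mediated hydrogen bonds
are found).  Acceptors: any oxygen, plus the His ring nitrogens — His is
treated as both donor and acceptor at ND1/NE2 since protonation is unknown.

Salt bridges: Lys NZ / Arg NE, NH1, NH2 against Asp OD1, OD2 / Glu OE1, OE2,
minimum inter-group distance within ``sb_max`` (default 4.0 A), reported once
per residue pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from epimimic.structure_io import Atom, Residue, ResidueID, Selection, SelectionError, StructureModel

__all__ = [
    "ContactCriteria",
    "AtomRef",
    "HBond",
    "SaltBridge",
    "find_hbonds",
    "find_salt_bridges",
]

_BOND_CUTOFF = 1.8  # heavy-atom covalent bond length upper bound, A

_HYDROXYL_DONORS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}
_SUGAR_NON_HYDROXYL_O = {"O5", "O7"}  # pyranose ring O and N-acetyl carbonyl
_BASIC_GROUPS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_ACIDIC_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


@dataclass(frozen=True)
class ContactCriteria:
    d_max: float = 3.5
    angle_min: float = 90.0
    sb_max: float = 4.0

    def __post_init__(self) -> None:
        if min(self.d_max, self.angle_min, self.sb_max) <= 0:
            raise ValueError("all contact criteria must be positive")


@dataclass(frozen=True)
class AtomRef:
    residue: ResidueID
    resname: str
    atom: str

    def __str__(self) -> str:
        return f"{self.resname} {self.residue}.{self.atom}"


@dataclass(frozen=True)
class HBond:
    donor: AtomRef
    acceptor: AtomRef
    distance: float
    angle: float | None  # best antecedent-donor-acceptor angle; None if donor has no antecedent


@dataclass(frozen=True)
class SaltBridge:
    basic: ResidueID
    acidic: ResidueID
    basic_resname: str
    acidic_resname: str
    distance: float  # minimum inter-group heavy-atom distance


def _is_donor(res: Residue, atom: Atom) -> bool:
    if atom.element == "N":
        return not (res.name == "PRO" and atom.name == "N")
    if atom.element == "O":
        if (res.name, atom.name) in _HYDROXYL_DONORS:
            return True
        if res.is_hetero and atom.name not in _SUGAR_NON_HYDROXYL_O:
            return True
    return False


def _is_acceptor(res: Residue, atom: Atom) -> bool:
    if atom.element == "O":
        return True
    if atom.element == "N" and res.name == "HIS" and atom.name in ("ND1", "NE2"):
        return True
    return False


def _antecedents(res: Residue, atom: Atom) -> list[Atom]:
    return [
        other
        for other in res.atoms
        if other is not atom and np.linalg.norm(other.xyz - atom.xyz) <= _BOND_CUTOFF
    ]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _typed_atoms(selection: Selection, predicate) -> list[tuple[Residue, Atom]]:
    return [(res, atom) for res, atom in selection.atoms() if predicate(res, atom)]


def _check_disjoint(side_a: Selection, side_b: Selection) -> None:
    overlap = side_a.atom_keys() & side_b.atom_keys()
    if overlap:
        raise SelectionError(f"sides overlap on {len(overlap)} atoms")


def _cross_pairs(
    donors: list[tuple[Residue, Atom]],
    acceptors: list[tuple[Residue, Atom]],
    cutoff: float,
    method: str,
) -> list[tuple[int, int, float]]:
    """(donor index, acceptor index, distance) for all pairs within cutoff."""
    if not donors or not acceptors:
        return []
    d_xyz = np.array([a.xyz for _, a in donors])
    a_xyz = np.array([a.xyz for _, a in acceptors])
    out: list[tuple[int, int, float]] = []
    if method == "brute":
        dist = np.linalg.norm(d_xyz[:, None, :] - a_xyz[None, :, :], axis=-1)
        for i, j in zip(*np.nonzero(dist <= cutoff)):
            # same per-pair expression as the fast path, so results are bitwise equal
            out.append((int(i), int(j), float(np.linalg.norm(d_xyz[i] - a_xyz[j]))))
    else:
        tree = cKDTree(a_xyz)
        for i, neighbors in enumerate(tree.query_ball_point(d_xyz, cutoff)):
            for j in neighbors:
                out.append((i, int(j), float(np.linalg.norm(d_xyz[i] - a_xyz[j]))))
    return out


def find_hbonds(
    model: StructureModel,
    side_a: Selection,
    side_b: Selection,
    criteria: ContactCriteria | None = None,
    method: str = "binned",
) -> list[HBond]:
    """All cross-interface hydrogen bonds under the geometric criteria.

    ``method='brute'`` forces the all-pairs scan (the oracle the fast spatial
    search is contractually identical to).  A donor with no covalently bonded
    heavy atom in its residue (possible only in abstract single-atom fixtures)
    is accepted without an angle check.
    """
    criteria = criteria or ContactCriteria()
    _check_disjoint(side_a, side_b)

    bonds: dict[tuple[AtomRef, AtomRef], HBond] = {}
    for donor_side, acceptor_side in ((side_a, side_b), (side_b, side_a)):
        donors = _typed_atoms(donor_side, _is_donor)
        acceptors = _typed_atoms(acceptor_side, _is_acceptor)
        for i, j, dist in _cross_pairs(donors, acceptors, criteria.d_max, method):
            d_res, d_atom = donors[i]
            a_res, a_atom = acceptors[j]
            antecedents = _antecedents(d_res, d_atom)
            if antecedents:
                best = max(_angle_deg(ant.xyz, d_atom.xyz, a_atom.xyz) for ant in antecedents)
                if best < criteria.angle_min:
                    continue
                angle: float | None = best
            else:
                angle = None
            key = (
                AtomRef(d_res.id, d_res.name, d_atom.name),
                AtomRef(a_res.id, a_res.name, a_atom.name),
            )
            if key not in bonds:
                bonds[key] = HBond(donor=key[0], acceptor=key[1], distance=dist, angle=angle)
    return sorted(bonds.values(), key=lambda h: (h.donor.residue, h.donor.atom, h.acceptor.residue, h.acceptor.atom))


def find_salt_bridges(
    model: StructureModel,
    side_a: Selection,
    side_b: Selection,
    criteria: ContactCriteria | None = None,
) -> list[SaltBridge]:
    """Cross-interface Lys/Arg vs Asp/Glu bridges, one per residue pair."""
    criteria = criteria or ContactCriteria()
    _check_disjoint(side_a, side_b)

    def _groups(selection: Selection, table: dict) -> list[tuple[Residue, np.ndarray]]:
        out = []
        for res in selection.residues:
            names = table.get(res.name)
            if not names:
                continue
            xyz = [res.get_atom(n).xyz for n in names if res.get_atom(n) is not None]
            if xyz:
                out.append((res, np.array(xyz)))
        return out

    bridges: dict[tuple[ResidueID, ResidueID], SaltBridge] = {}
    for basic_side, acidic_side in ((side_a, side_b), (side_b, side_a)):
        for basic_res, basic_xyz in _groups(basic_side, _BASIC_GROUPS):
            for acidic_res, acidic_xyz in _groups(acidic_side, _ACIDIC_GROUPS):
                dmin = float(
                    np.min(np.linalg.norm(basic_xyz[:, None, :] - acidic_xyz[None, :, :], axis=-1))
                )
                if dmin <= criteria.sb_max:
                    key = (basic_res.id, acidic_res.id)
                    if key not in bridges:
                        bridges[key] = SaltBridge(
                            basic=basic_res.id,
                            acidic=acidic_res.id,
                            basic_resname=basic_res.name,
                            acidic_resname=acidic_res.name,
                            distance=dmin,
                        )
    return sorted(bridges.values(), key=lambda s: (s.basic, s.acidic))
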