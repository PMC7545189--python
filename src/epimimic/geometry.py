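"""Rigid superposition, backbone r.m.s.d., domain axes and crossing angles.

Superposition is the Kabsch least-squares fit (SVD with determinant
correction, so the result is always a proper rotation).  A domain's axis is
the first principal component of its Cα cloud, sign-fixed so that it points
from the N- towards the C-terminus; the crossing angle between a receptor IgV
domain and its ligand's IgV domain is the angle between the two axes over the
full [0, 180] degree range — with the N->C orientation convention the sign of
the dot product is meaningful, which is what lets structurally distinct
binding orientations (e.g. ~90 vs ~150 degrees) be told apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from epimimic.structure_io import Chain, ResidueMapping, Selection

__all__ = [
    "SuperpositionResult",
    "DomainAxis",
    "GeometryError",
    "superpose",
    "backbone_rmsd",
    "principal_axis",
    "axis_angle",
    "crossing_angle",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class GeometryError(ValueError):
    """Raised for degenerate geometric inputs."""


@dataclass
class SuperpositionResult:
    """Rigid transform x -> R @ x + t mapping the mobile coordinates onto the
    reference, with the residual r.m.s.d. after the fit."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, float)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation is not proper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class DomainAxis:
    centroid: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("axis direction must be a unit vector")


def _check_nondegenerate(centered: np.ndarray, what: str) -> None:
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise GeometryError(f"{what} coordinates are (near-)collinear; superposition is ill-posed")


def superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Kabsch fit of ``mobile`` onto ``reference`` (paired N x 3 coordinates)."""
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate arrays must share an (N, 3) shape, got {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError(f"need at least 3 paired atoms, got {n}")

    c_ref = ref.mean(axis=0)
    c_mob = mob.mean(axis=0)
    ref0 = ref - c_ref
    mob0 = mob - c_mob
    _check_nondegenerate(ref0, "reference")
    _check_nondegenerate(mob0, "mobile")

    h = mob0.T @ ref0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = c_ref - rot @ c_mob
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=n)


def backbone_rmsd(
    chain_a: Chain | Selection,
    chain_b: Chain | Selection,
    mapping: ResidueMapping,
    atom_names: tuple[str, ...] = BACKBONE_ATOMS,
) -> float:
    """Optimal-superposition r.m.s.d. over mapped backbone (N, CA, C, O) pairs.

    Atoms missing on either side of a residue pair (common for terminal O)
    are dropped pairwise rather than failing.
    """
    if len(mapping) == 0:
        raise ValueError("empty residue mapping")
    res_a = {r.id: r for r in (chain_a.residues if hasattr(chain_a, "residues") else chain_a)}
    res_b = {r.id: r for r in (chain_b.residues if hasattr(chain_b, "residues") else chain_b)}
    coords_a, coords_b = [], []
    for rid_a, rid_b in mapping.pairs:
        ra, rb = res_a.get(rid_a), res_b.get(rid_b)
        if ra is None or rb is None:
            continue
        for name in atom_names:
            aa, ab = ra.get_atom(name), rb.get_atom(name)
            if aa is not None and ab is not None:
                coords_a.append(aa.xyz)
                coords_b.append(ab.xyz)
    if len(coords_a) < 3:
        raise GeometryError(f"only {len(coords_a)} paired backbone atoms; need >= 3")
    return superpose(np.array(coords_a), np.array(coords_b)).rmsd


def principal_axis(selection: Selection) -> DomainAxis:
    """First principal component of the Cα cloud, oriented N -> C.

    The sign convention: the direction's dot product with (C-terminal Cα
    minus N-terminal Cα) is non-negative, termini taken in selection order.
    """
    ca = selection.ca_coords()
    if len(ca) < 4:
        raise GeometryError(f"need >= 4 CA atoms for a domain axis, got {len(ca)}")
    centroid = ca.mean(axis=0)
    centered = ca - centroid
    _, _, vt = np.linalg.svd(centered)
    direction = vt[0] / np.linalg.norm(vt[0])
    if float(np.dot(direction, ca[-1] - ca[0])) < 0:
        direction = -direction
    return DomainAxis(centroid=centroid, direction=direction)


def axis_angle(a1: DomainAxis, a2: DomainAxis) -> float:
    """Angle between two oriented axes, in degrees over [0, 180]."""
    cosang = float(np.clip(np.dot(a1.direction, a2.direction), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def crossing_angle(receptor_domain: Selection, ligand_domain: Selection) -> float:
    """Crossing (approach) angle between two IgV domains' principal axes."""
    return axis_angle(principal_axis(receptor_domain), principal_axis(ligand_domain))
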