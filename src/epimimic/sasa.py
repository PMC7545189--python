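"""Shrake-Rupley solvent-accessible surface area.

Every buried-surface-area number downstream rests on this primitive, so it is
kept deterministic and auditable: sphere points come from a golden-section
spiral (no RNG), the van der Waals radii are a fixed per-element table, and
the binned neighbour search is contractually identical to the all-pairs scan
(exposed here as ``method='brute'`` so tests can enforce it).

A point on atom *i*'s expanded sphere (radius r_i + probe) counts as
accessible iff it lies strictly outside every neighbour's expanded sphere;
the atom's SASA is the accessible fraction times the expanded sphere area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np

if TYPE_CHECKING:
    from epimimic.structure_io import ResidueID, Selection

__all__ = ["SasaParams", "SASAResult", "SasaError", "compute_sasa", "sphere_points", "DEFAULT_RADII"]

# Per-element van der Waals radii (Angstrom), NACCESS/Chothia-style values
# simplified to one radius per element; saccharide C/O share the protein values.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.80,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


class SasaError(ValueError):
    """Raised for unusable SASA inputs (no atoms, unknown element)."""


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be > 0")
        if self.n_points < 60:
            raise ValueError("n_points must be >= 60")

    def radius_of(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise SasaError(f"no van der Waals radius for element {element!r}") from None


@dataclass
class SASAResult:
    """Per-atom areas aligned with the selection's atom order, plus rollups."""

    atom_areas: np.ndarray
    residue_areas: dict["ResidueID", float]
    total: float
    params: SasaParams

    def __post_init__(self) -> None:
        if np.any(self.atom_areas < 0):
            raise ValueError("negative per-atom area")


def sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points via the golden-section spiral."""
    i = np.arange(n, dtype=float) + 0.5
    cos_phi = 1.0 - 2.0 * i / n
    sin_phi = np.sqrt(np.clip(1.0 - cos_phi**2, 0.0, None))
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.cos(theta) * sin_phi, np.sin(theta) * sin_phi, cos_phi])


def _neighbor_lists_binned(coords: np.ndarray, expanded: np.ndarray) -> list[np.ndarray]:
    """Indices of atoms whose expanded spheres can occlude each atom.

    Spatial binning with cell size 2*max(expanded radius); candidate pairs are
    filtered by the exact criterion d < R_i + R_j, so the result equals the
    all-pairs scan.
    """
    n = len(coords)
    cell = 2.0 * float(expanded.max())
    keys = np.floor(coords / cell).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for idx in range(n):
        buckets.setdefault(tuple(keys[idx]), []).append(idx)

    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    out: list[np.ndarray] = []
    for idx in range(n):
        kx, ky, kz = keys[idx]
        cand: list[int] = []
        for dx, dy, dz in offsets:
            cand.extend(buckets.get((kx + dx, ky + dy, kz + dz), ()))
        cand_arr = np.array([j for j in cand if j != idx], dtype=int)
        if cand_arr.size:
            d = np.linalg.norm(coords[cand_arr] - coords[idx], axis=1)
            cand_arr = cand_arr[d < expanded[cand_arr] + expanded[idx]]
        out.append(cand_arr)
    return out


def _neighbor_lists_brute(coords: np.ndarray, expanded: np.ndarray) -> list[np.ndarray]:
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cut = expanded[:, None] + expanded[None, :]
    out = []
    for idx in range(n):
        mask = (d[idx] < cut[idx])
        mask[idx] = False
        out.append(np.nonzero(mask)[0])
    return out


def compute_sasa(
    selection: "Selection",
    params: SasaParams | None = None,
    method: str = "binned",
) -> SASAResult:
    """Per-atom Shrake-Rupley SASA of a selection, taken in isolation.

    Only atoms inside the selection occlude each other; computing a side of a
    complex "alone" is therefore just SASA of that side's selection, and the
    whole complex is SASA of the union selection.
    """
    pairs = selection.atoms()
    if not pairs:
        raise SasaError("selection contains no atoms")
    params = params or SasaParams()

    coords = np.array([a.xyz for _, a in pairs], dtype=float)
    expanded = np.array(
        [params.radius_of(a.element) + params.probe_radius for _, a in pairs], dtype=float
    )
    unit = sphere_points(params.n_points)

    if method == "binned":
        neighbors = _neighbor_lists_binned(coords, expanded)
    elif method == "brute":
        neighbors = _neighbor_lists_brute(coords, expanded)
    else:
        raise ValueError(f"unknown method {method!r}")

    areas = np.empty(len(pairs), dtype=float)
    for idx in range(len(pairs)):
        nb = neighbors[idx]
        sphere_area = 4.0 * np.pi * expanded[idx] ** 2
        if nb.size == 0:
            areas[idx] = sphere_area
            continue
        pts = coords[idx] + expanded[idx] * unit  # (n_points, 3)
        diff = pts[:, None, :] - coords[nb][None, :, :]
        d2 = np.einsum("pnk,pnk->pn", diff, diff)
        # relative epsilon: points landing exactly on a neighbour's surface
        # (degenerate coincident-sphere geometry) count as buried
        accessible = np.all(d2 > expanded[nb] ** 2 * (1.0 + 1e-9), axis=1)
        areas[idx] = accessible.mean() * sphere_area

    residue_areas: dict = {}
    for (res, _), area in zip(pairs, areas):
        residue_areas[res.id] = residue_areas.get(res.id, 0.0) + float(area)

    return SASAResult(
        atom_areas=areas,
        residue_areas=residue_areas,
        total=float(areas.sum()),
        params=params,
    )
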