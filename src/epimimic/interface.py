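"""Buried surface area, interface footprints, and region contributions.

BSA is computed per side of a binary interface as the loss of solvent
accessibility on complex formation: for each atom of side A,
``BSA = SASA(A alone) - SASA(A in A union B)``, and likewise for side B.  The
two per-side totals are reported separately (the per-ectodomain convention);
no halving or summing across sides is applied.  Because both evaluations use
the same deterministic sphere-point set, per-atom BSA is non-negative by
construction.

A *footprint* is the set of a side's residues whose BSA strictly exceeds a
threshold tau (default 1 A^2) — the unit of epitope/footprint comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from epimimic.sasa import SasaParams, compute_sasa
from epimimic.structure_io import ResidueID, Selection, SelectionError, StructureModel

__all__ = [
    "InterfaceMap",
    "Footprint",
    "ContributionResult",
    "buried_surface",
    "interface_residues",
    "region_contribution",
]


@dataclass
class InterfaceMap:
    """Per-residue buried surface area for both sides of a binary interface."""

    per_residue_a: dict[ResidueID, float]
    per_residue_b: dict[ResidueID, float]
    total_a: float
    total_b: float
    resnames: dict[ResidueID, str]
    params: SasaParams
    label_a: str = "A"
    label_b: str = "B"

    def side(self, which: str) -> dict[ResidueID, float]:
        if which.upper() == "A":
            return self.per_residue_a
        if which.upper() == "B":
            return self.per_residue_b
        raise ValueError(f"side must be 'A' or 'B', got {which!r}")

    def side_total(self, which: str) -> float:
        return self.total_a if which.upper() == "A" else self.total_b

    def to_frame(self, tau: float = 0.0) -> pd.DataFrame:
        """Per-residue BSA table (one row per residue with BSA > tau)."""
        rows = []
        for side_label, per_res in ((self.label_a, self.per_residue_a), (self.label_b, self.per_residue_b)):
            for rid, bsa in sorted(per_res.items()):
                if bsa > tau:
                    rows.append(
                        {
                            "side": side_label,
                            "chain": rid.chain,
                            "seqnum": rid.seqnum,
                            "icode": rid.icode,
                            "resname": self.resnames.get(rid, ""),
                            "bsa": bsa,
                        }
                    )
        return pd.DataFrame(rows, columns=["side", "chain", "seqnum", "icode", "resname", "bsa"])


@dataclass
class Footprint:
    """Residues of one molecule with BSA strictly above tau at an interface."""

    label: str
    residues: dict[ResidueID, float]
    tau: float = 1.0

    def __post_init__(self) -> None:
        bad = {rid: v for rid, v in self.residues.items() if v <= self.tau}
        if bad:
            raise ValueError(f"footprint contains residues at or below tau={self.tau}: {bad}")

    def __contains__(self, rid: ResidueID) -> bool:
        return rid in self.residues

    def __len__(self) -> int:
        return len(self.residues)

    def residue_ids(self) -> set[ResidueID]:
        return set(self.residues)


@dataclass
class ContributionResult:
    region_area: float
    side_total: float
    fraction: float


def buried_surface(
    model: StructureModel,
    side_a: Selection,
    side_b: Selection,
    params: SasaParams | None = None,
) -> InterfaceMap:
    """Per-side BSA from three SASA evaluations (A alone, B alone, A union B)."""
    params = params or SasaParams()
    overlap = side_a.atom_keys() & side_b.atom_keys()
    if overlap:
        raise SelectionError(f"sides overlap on {len(overlap)} atoms, e.g. {sorted(overlap)[:3]}")

    sasa_a = compute_sasa(side_a, params)
    sasa_b = compute_sasa(side_b, params)
    union = Selection(model, side_a.residues + side_b.residues, label="complex")
    sasa_ab = compute_sasa(union, params)

    n_atoms_a = len(side_a.atoms())
    bsa_atoms_a = sasa_a.atom_areas - sasa_ab.atom_areas[:n_atoms_a]
    bsa_atoms_b = sasa_b.atom_areas - sasa_ab.atom_areas[n_atoms_a:]

    def _per_residue(selection: Selection, atom_bsa) -> dict[ResidueID, float]:
        acc: dict[ResidueID, float] = {}
        for (res, _), v in zip(selection.atoms(), atom_bsa):
            acc[res.id] = acc.get(res.id, 0.0) + float(max(v, 0.0))
        return acc

    per_res_a = _per_residue(side_a, bsa_atoms_a)
    per_res_b = _per_residue(side_b, bsa_atoms_b)
    resnames = {r.id: r.name for r in side_a.residues + side_b.residues}

    return InterfaceMap(
        per_residue_a=per_res_a,
        per_residue_b=per_res_b,
        total_a=sum(per_res_a.values()),
        total_b=sum(per_res_b.values()),
        resnames=resnames,
        params=params,
        label_a=side_a.label or "A",
        label_b=side_b.label or "B",
    )


def interface_residues(imap: InterfaceMap, tau: float = 1.0) -> tuple[Footprint, Footprint]:
    """Both sides' footprints at threshold tau (strict inequality BSA > tau)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    fp_a = Footprint(imap.label_a, {r: v for r, v in imap.per_residue_a.items() if v > tau}, tau)
    fp_b = Footprint(imap.label_b, {r: v for r, v in imap.per_residue_b.items() if v > tau}, tau)
    return fp_a, fp_b


def region_contribution(imap: InterfaceMap, side: str, region: Selection) -> ContributionResult:
    """BSA contributed by a region (e.g. a loop motif) of one side.

    The fraction is region BSA over that side's total BSA; a region of an
    interface-free side reports area 0 and fraction 0.
    """
    per_res = imap.side(side)
    region_ids = region.residue_ids()
    missing = region_ids - set(per_res)
    if missing:
        raise SelectionError(
            f"region residues not part of side {side}: {sorted(str(r) for r in missing)[:5]}"
        )
    area = sum(per_res[rid] for rid in region_ids)
    total = imap.side_total(side)
    fraction = area / total if total > 0 else 0.0
    return ContributionResult(region_area=area, side_total=total, fraction=fraction)
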