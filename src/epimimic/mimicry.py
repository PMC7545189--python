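"""Receptor/ligand mimicry scoring for therapeutic antibodies.

The statistic: of the residues a molecule buries against its natural binding
partner (BSA > tau, tau = 1 A^2 by default), what fraction is also contacted
— by the same BSA > tau rule — when an antibody binds that molecule instead?
A fraction near 1 means the antibody's paratope sits on essentially the same
surface the natural partner uses, i.e. it achieves receptor/ligand mimicry.

The two complexes usually come from different crystal forms, so residues are
matched through a sequence-alignment :class:`~epimimic.structure_io.ResidueMapping`
rather than by raw author numbering; natural-interface residues with no
mapped counterpart in the antibody complex stay in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from epimimic.interface import Footprint, InterfaceMap
from epimimic.structure_io import ResidueID, ResidueMapping

__all__ = ["MimicryScore", "MimicryError", "mimicry_fraction", "footprint_table"]


class MimicryError(ValueError):
    """Raised when a mimicry score cannot be formed (empty natural footprint)."""


@dataclass
class MimicryScore:
    fraction: float
    natural_residues: list[ResidueID]
    contacted_residues: list[ResidueID]
    molecule: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if not set(self.contacted_residues) <= set(self.natural_residues):
            raise ValueError("contacted residues must be a subset of the natural footprint")

    @property
    def n_interface(self) -> int:
        return len(self.natural_residues)

    @property
    def n_contacted(self) -> int:
        return len(self.contacted_residues)

    def to_dict(self) -> dict:
        return {
            "molecule": self.molecule,
            "f": self.fraction,
            "n_interface": self.n_interface,
            "n_contacted": self.n_contacted,
            "residues": [str(r) for r in self.natural_residues],
            "contacted": [str(r) for r in self.contacted_residues],
        }


def mimicry_fraction(
    natural: Footprint,
    antibody: Footprint,
    mapping: ResidueMapping | None = None,
    molecule: str = "",
) -> MimicryScore:
    """Fraction of the natural footprint contacted in the antibody complex.

    ``mapping`` carries natural-complex residue ids to antibody-complex ids;
    ``None`` means the two complexes share numbering (identity mapping).
    """
    if len(natural) == 0:
        raise MimicryError("natural footprint is empty; mimicry fraction undefined")
    natural_ids = sorted(natural.residue_ids())
    contacted = []
    for rid in natural_ids:
        counterpart = mapping.get(rid) if mapping is not None else rid
        if counterpart is not None and counterpart in antibody:
            contacted.append(rid)
    return MimicryScore(
        fraction=len(contacted) / len(natural_ids),
        natural_residues=natural_ids,
        contacted_residues=contacted,
        molecule=molecule,
    )


def footprint_table(
    natural_imap: InterfaceMap,
    natural_side: str,
    antibody_imap: InterfaceMap,
    antibody_side: str,
    mapping: ResidueMapping | None = None,
    tau: float = 1.0,
) -> pd.DataFrame:
    """Per-residue BSA comparison of one molecule across its two complexes.

    One row per residue in either footprint (BSA > tau in either complex),
    keyed by the natural-complex residue id, with the residue's BSA against
    the natural partner, its BSA against the antibody, and a flag for
    membership in both footprints.
    """
    nat = natural_imap.side(natural_side)
    ab = antibody_imap.side(antibody_side)

    rows = []
    seen_ab: set[ResidueID] = set()
    for rid in sorted(nat):
        counterpart = mapping.get(rid) if mapping is not None else rid
        bsa_nat = nat[rid]
        bsa_ab = ab.get(counterpart, 0.0) if counterpart is not None else 0.0
        if counterpart is not None:
            seen_ab.add(counterpart)
        if bsa_nat > tau or bsa_ab > tau:
            rows.append((rid, natural_imap.resnames.get(rid, ""), bsa_nat, bsa_ab))
    # antibody-contacted residues absent from the natural complex's numbering
    for rid in sorted(set(ab) - seen_ab):
        back = mapping.get_reverse(rid) if mapping is not None else rid
        if back is not None and back in nat:
            continue  # already emitted above
        if ab[rid] > tau:
            label = back if back is not None else rid
            rows.append((label, antibody_imap.resnames.get(rid, ""), 0.0, ab[rid]))

    frame = pd.DataFrame(
        [
            {
                "chain": rid.chain,
                "seqnum": rid.seqnum,
                "icode": rid.icode,
                "resname": name,
                "bsa_natural": bn,
                "bsa_antibody": ba,
                "shared": bn > tau and ba > tau,
            }
            for rid, name, bn, ba in rows
        ],
        columns=["chain", "seqnum", "icode", "resname", "bsa_natural", "bsa_antibody", "shared"],
    )
    return frame.sort_values(["chain", "seqnum", "icode"], ignore_index=True)
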