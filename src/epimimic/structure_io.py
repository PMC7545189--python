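"""Macromolecular structure parsing, selection, and residue mapping.

A deliberately small hierarchical container (:class:`StructureModel` ->
:class:`Chain` -> :class:`Residue` -> :class:`Atom`) backs all downstream
geometry.  Parsing of PDB and mmCIF dialects is delegated to :mod:`gemmi`;
at load time waters are removed, hydrogens are dropped, and alternate
conformers are collapsed to the highest-occupancy one (ties broken in favour
of altloc ``A``) so that every later calculation sees a single deterministic
heavy-atom model.  Author (deposited) residue numbering is preserved: it is
what interface residues are reported and compared by.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align
from Bio.Data.IUPACData import protein_letters_3to1_extended as _3TO1

__all__ = [
    "Atom",
    "Residue",
    "ResidueID",
    "Chain",
    "StructureModel",
    "Selection",
    "ResidueMapping",
    "ParseError",
    "SelectionError",
    "parse_structure",
    "write_pdb",
    "select",
    "map_residues",
    "one_letter_sequence",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "DIS"})


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


class SelectionError(ValueError):
    """Raised when a selection references missing chains or resolves empty."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """Author-numbered residue identity: (chain, seqnum, insertion code)."""

    chain: str
    seqnum: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A114" or "A114B"
        return f"{self.chain}{self.seqnum}{self.icode}"


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    id: ResidueID
    name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.id} has no atoms")

    @property
    def is_hetero(self) -> bool:
        return all(a.is_hetero for a in self.atoms)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class StructureModel:
    """One model's worth of chains; the substrate of all geometry."""

    chains: list[Chain] = field(default_factory=list)
    accession: str | None = None

    def __post_init__(self) -> None:
        seen: set[ResidueID] = set()
        for ch in self.chains:
            for res in ch:
                if res.id in seen:
                    raise ValueError(f"duplicate residue id {res.id}")
                seen.add(res.id)

    def get_chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in model (have {[c.id for c in self.chains]})")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def _atom_key(res: Residue, atom: Atom) -> tuple:
    return (res.id.chain, res.id.seqnum, res.id.icode, atom.name)


@dataclass
class Selection:
    """A resolved, ordered, non-empty set of residues of one model."""

    model: StructureModel
    residues: list[Residue]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SelectionError(f"selection {self.label!r} resolved to zero residues")

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for _, a in self.atoms()], dtype=float)

    def residue_ids(self) -> set[ResidueID]:
        return {r.id for r in self.residues}

    def atom_keys(self) -> set[tuple]:
        return {_atom_key(r, a) for r, a in self.atoms()}

    def ca_coords(self) -> np.ndarray:
        """Cα coordinates in residue order (residues lacking CA are skipped)."""
        pts = [r.get_atom("CA").xyz for r in self.residues if r.get_atom("CA") is not None]
        return np.array(pts, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# parsing


def _validate_pdb_text(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: unparseable coordinates") from exc


def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, tie -> altloc 'A'."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept: list[Atom] = []
    for name in order:
        group = by_name[name]
        if len(group) == 1:
            kept.append(group[0])
            continue
        best_occ = max(a.occupancy for a in group)
        tied = [a for a in group if a.occupancy == best_occ]
        tied.sort(key=lambda a: (a.altloc != "A", a.altloc))
        kept.append(tied[0])
    return kept


def _from_gemmi(st: gemmi.Structure, accession: str | None) -> StructureModel:
    if len(st) == 0:
        raise ParseError("structure contains no models")
    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            if gres.name.upper() in WATER_NAMES or gres.is_water():
                continue
            is_het = gres.het_flag == "H"
            atoms: list[Atom] = []
            for gat in gres:
                elem = gat.element.name.upper()
                if elem in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=gat.name,
                        element=elem,
                        xyz=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                        occupancy=min(max(gat.occ, 0.0), 1.0),
                        altloc=gat.altloc if gat.altloc != "\x00" else "",
                        bfactor=gat.b_iso,
                        is_hetero=is_het,
                    )
                )
            atoms = _collapse_altlocs(atoms)
            if not atoms:
                continue
            rid = ResidueID(gch.name, gres.seqid.num, (gres.seqid.icode or " ").strip())
            residues.append(Residue(rid, gres.name.upper(), atoms))
        if residues:
            chains.append(Chain(gch.name, residues))
    if not chains:
        raise ParseError("structure contains no non-water residues")
    return StructureModel(chains=chains, accession=accession)


def parse_structure(text: str, fmt: str = "pdb", accession: str | None = None) -> StructureModel:
    """Parse PDB or mmCIF text into a :class:`StructureModel`.

    Waters are removed, hydrogens dropped, alternate locations collapsed to the
    highest-occupancy conformer (tie -> altloc ``A``).  Author residue
    numbering and hetero residues (glycans, ions) are preserved.
    """
    fmt = fmt.lower()
    if fmt == "pdb":
        _validate_pdb_text(text)
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"PDB parse failed: {exc}") from exc
    elif fmt in ("cif", "mmcif"):
        try:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"mmCIF parse failed: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")
    st.setup_entities()
    return _from_gemmi(st, accession)


def write_pdb(model: StructureModel) -> str:
    """Serialize a model as fixed-column PDB text (for fixtures and exchange)."""
    lines: list[str] = []
    serial = 0
    for ch in model.chains:
        for res in ch:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                name = atom.name
                if len(name) < 4:
                    name = f" {name:<3s}"
                x, y, z = atom.xyz
                lines.append(
                    f"{record}{serial:5d} {name:<4s}{atom.altloc or ' ':1s}{res.name:>3s} "
                    f"{ch.id[:1]:1s}{res.id.seqnum:4d}{res.id.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# selection


def select(
    model: StructureModel,
    chains: str | Sequence[str] | None = None,
    ranges: Sequence[tuple[str, int, int]] | None = None,
    include_hetero: bool = True,
    label: str = "",
) -> Selection:
    """Resolve a chain/range/hetero predicate to an ordered residue set.

    ``ranges`` entries are inclusive ``(chain, first, last)`` author-number
    intervals; when given, only residues inside some interval are kept.
    An empty result raises :class:`SelectionError` naming the predicate.
    """
    if isinstance(chains, str):
        chains = [chains]
    wanted_chains = set(chains) if chains is not None else None
    if ranges:
        for cid, _, _ in ranges:
            if cid not in model.chain_ids:
                raise SelectionError(f"range references missing chain {cid!r}")
        if wanted_chains is None:
            wanted_chains = {cid for cid, _, _ in ranges}
    if wanted_chains is not None:
        missing = wanted_chains - set(model.chain_ids)
        if missing:
            raise SelectionError(f"chains {sorted(missing)} not present in model")

    residues: list[Residue] = []
    for ch in model.chains:
        if wanted_chains is not None and ch.id not in wanted_chains:
            continue
        for res in ch:
            if not include_hetero and res.is_hetero:
                continue
            if ranges and not any(
                cid == ch.id and lo <= res.id.seqnum <= hi for cid, lo, hi in ranges
            ):
                continue
            residues.append(res)
    if not residues:
        raise SelectionError(
            f"selection resolved empty (chains={chains}, ranges={ranges}, "
            f"include_hetero={include_hetero})"
        )
    return Selection(model, residues, label=label or (",".join(sorted(wanted_chains)) if wanted_chains else "all"))


# ---------------------------------------------------------------------------
# residue mapping (cross-crystal correspondence)


def one_letter_sequence(residues: Iterable[Residue]) -> str:
    """One-letter sequence of the standard (non-hetero) residues; unknown -> X."""
    letters = []
    for res in residues:
        if res.is_hetero:
            continue
        letters.append(_3TO1.get(res.name.capitalize(), "X"))
    return "".join(letters)


@dataclass
class ResidueMapping:
    """One-to-one correspondence between residues of two chains."""

    pairs: list[tuple[ResidueID, ResidueID]]
    score: float
    identity: float

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("residue mapping is not one-to-one")
        self._forward: dict[ResidueID, ResidueID] = dict(self.pairs)
        self._backward: dict[ResidueID, ResidueID] = {b: a for a, b in self.pairs}

    def get(self, rid: ResidueID) -> ResidueID | None:
        return self._forward.get(rid)

    def get_reverse(self, rid: ResidueID) -> ResidueID | None:
        return self._backward.get(rid)

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity_mapping(cls, residues: Iterable[Residue]) -> "ResidueMapping":
        pairs = [(r.id, r.id) for r in residues]
        return cls(pairs=pairs, score=float(len(pairs)), identity=1.0)


def _polymer_residues(chain: Chain | Selection) -> list[Residue]:
    residues = chain.residues if isinstance(chain, (Chain, Selection)) else list(chain)
    return [r for r in residues if not r.is_hetero]


def map_residues(
    chain_a: Chain | Selection,
    chain_b: Chain | Selection,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> ResidueMapping:
    """Global (Needleman-Wunsch) alignment of two chains with identity scoring.

    Match scores 1, mismatch 0; aligned non-gap columns become residue pairs.
    Used to carry a molecule's footprint between crystal forms whose author
    numbering may disagree.
    """
    res_a = _polymer_residues(chain_a)
    res_b = _polymer_residues(chain_b)
    seq_a = one_letter_sequence(res_a)
    seq_b = one_letter_sequence(res_b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align: empty polymer sequence")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(seq_a, seq_b)[0]

    pairs: list[tuple[ResidueID, ResidueID]] = []
    n_match = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            ia, ib = a_start + off, b_start + off
            pairs.append((res_a[ia].id, res_b[ib].id))
            if seq_a[ia] == seq_b[ib]:
                n_match += 1
    identity = n_match / len(pairs) if pairs else 0.0
    return ResidueMapping(pairs=pairs, score=float(aln.score), identity=identity)
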