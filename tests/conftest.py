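"""Shared fixtures: hand-written PDB snippets and toy-complex builders.

All structural fixtures are synthetic and generated programmatically; the
PDB snippets below are minimal hand-laid records for exercising parser rules
(altlocs, waters, glycans) that the generators do not produce.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Data.IUPACData import protein_letters_1to3

from epimimic.structure_io import Atom, Chain, Residue, ResidueID, StructureModel


def pdb_line(
    record: str,
    serial: int,
    name: str,
    resname: str,
    chain: str,
    seq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    altloc: str = " ",
    icode: str = " ",
    occ: float = 1.0,
    b: float = 0.0,
) -> str:
    """One fixed-column coordinate record."""
    atom_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:5d} {atom_field}{altloc}{resname:>3s} {chain}"
        f"{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def glycine_pdb() -> str:
    """Minimal one-residue, three-atom protein."""
    lines = [
        pdb_line("ATOM", 1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line("ATOM", 2, "CA", "GLY", "A", 1, 1.46, 0.0, 0.0, "C"),
        pdb_line("ATOM", 3, "C", "GLY", "A", 1, 2.0, 1.4, 0.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def altloc_pdb() -> str:
    """One CA in two conformers, occupancies 0.6 (B) and 0.4 (A)."""
    lines = [
        pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.46, 0.0, 0.0, "C", altloc="B", occ=0.6),
        pdb_line("ATOM", 3, "CA", "ALA", "A", 1, 1.50, 0.1, 0.0, "C", altloc="A", occ=0.4),
        pdb_line("ATOM", 4, "C", "ALA", "A", 1, 2.0, 1.4, 0.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def glyco_complex_pdb() -> str:
    """Two protein chains, two NAG glycan residues, five waters."""
    lines = []
    serial = 0

    def add(record, name, resname, chain, seq, x, y, z, element):
        nonlocal serial
        serial += 1
        lines.append(pdb_line(record, serial, name, resname, chain, seq, x, y, z, element))

    for i in range(3):  # chain A tripeptide
        add("ATOM", "N", "ALA", "A", i + 1, i * 3.8, 0.0, 0.0, "N")
        add("ATOM", "CA", "ALA", "A", i + 1, i * 3.8 + 1.4, 0.0, 0.0, "C")
        add("ATOM", "O", "ALA", "A", i + 1, i * 3.8 + 2.0, 1.2, 0.0, "O")
    for i in range(2):  # chain B dipeptide
        add("ATOM", "N", "GLY", "B", i + 1, i * 3.8, 8.0, 0.0, "N")
        add("ATOM", "CA", "GLY", "B", i + 1, i * 3.8 + 1.4, 8.0, 0.0, "C")
    for i, seq in enumerate((201, 202)):  # glycan on chain A
        add("HETATM", "C1", "NAG", "A", seq, i * 3.0, -5.0, 0.0, "C")
        add("HETATM", "O5", "NAG", "A", seq, i * 3.0 + 1.2, -5.8, 0.0, "O")
        add("HETATM", "O3", "NAG", "A", seq, i * 3.0 - 1.0, -6.2, 0.0, "O")
    for i in range(5):
        add("HETATM", "O", "HOH", "W", 301 + i, 20.0 + i * 3.0, 20.0, 0.0, "O")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_protein_chain(sequence: str, chain_id: str = "A", spacing: float = 3.8) -> Chain:
    """Chain with full backbone (N, CA, C, O) from a one-letter sequence."""
    residues = []
    for i, letter in enumerate(sequence):
        name = protein_letters_1to3.get(letter.upper(), "Ala").upper()
        base = np.array([i * spacing, 0.0, 0.0])
        atoms = [
            Atom("N", "N", base + [-1.46, 0.0, 0.0]),
            Atom("CA", "C", base),
            Atom("C", "C", base + [1.52, 0.0, 0.0]),
            Atom("O", "O", base + [2.05, 1.11, 0.0]),
        ]
        residues.append(Residue(ResidueID(chain_id, i + 1), name, atoms))
    return Chain(chain_id, residues)


def single_chain_model(sequence: str, chain_id: str = "A") -> StructureModel:
    return StructureModel(chains=[make_protein_chain(sequence, chain_id)])


def brute_force_alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = 0.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Max global alignment score by exhaustive enumeration (lengths <= ~7).

    Affine gap cost: a run of L gapped positions scores
    gap_open + (L - 1) * gap_extend, end gaps included.
    """
    best = -np.inf

    def rec(i: int, j: int, score: float, prev: str | None) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch), "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if prev == "D" else gap_open), "D")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if prev == "I" else gap_open), "I")

    rec(0, 0, 0.0, None)
    return float(best)
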