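"""Interface analysis of the deposited ICOS/ICOS-L and antibody complexes.

This driver reproduces the published interface characterisation — per-side
BSA footprints, FDPPPF/TKTKGS/glycan region contributions, the IgV crossing
angle, cross-crystal backbone r.m.s.d., contact counts, and the mimicry
fractions — on the deposited crystal structures (6X4G: ICOS/ICOS-L; 6X4T:
ICOS-L/prezalumab; 7JOO: ICOS/STIM003; 1I8L: CTLA-4/B7-1 comparator).

It requires the structures in data/structures/.  Run once with network:

    python analysis/08_deposited_structures.py --fetch

Without the files it prints what is missing and exits cleanly; no network
access happens unless --fetch is given.
"""

import argparse
import json
import sys
from pathlib import Path

from epimimic.contacts import find_hbonds, find_salt_bridges
from epimimic.geometry import backbone_rmsd, crossing_angle
from epimimic.interface import buried_surface, interface_residues, region_contribution
from epimimic.mimicry import mimicry_fraction
from epimimic.structure_io import (
    Selection,
    map_residues,
    one_letter_sequence,
    parse_structure,
    select,
)

ROOT = Path(__file__).resolve().parent.parent
STRUCTURES = ROOT / "data" / "structures"
ACCESSIONS = ("6X4G", "6X4T", "7JOO", "1I8L")
OUT = ROOT / "results"


def load(accession: str):
    path = STRUCTURES / f"{accession}.pdb"
    return parse_structure(path.read_text(), "pdb", accession=accession)


def chain_with_motif(model, motif):
    for chain in model.chains:
        if motif in one_letter_sequence(chain.residues):
            return chain
    raise KeyError(f"{model.accession}: no chain with motif {motif}")


def best_match(model, reference):
    scored = []
    for chain in model.chains:
        if one_letter_sequence(chain.residues):
            m = map_residues(reference, chain)
            scored.append((m.identity * len(m), chain))
    return max(scored, key=lambda t: t[0])[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fetch", action="store_true", help="download missing accessions")
    args = parser.parse_args()

    missing = [a for a in ACCESSIONS if not (STRUCTURES / f"{a}.pdb").exists()]
    if missing and args.fetch:
        from epimimic.fetch import fetch_structure

        for acc in missing:
            print(f"fetching {acc} ...")
            fetch_structure(acc, STRUCTURES)
        missing = []
    if missing:
        print(f"missing deposited structures: {', '.join(missing)}")
        print(f"run `python {sys.argv[0]} --fetch` once with network access")
        return

    report = {}

    natural = load("6X4G")
    icos = chain_with_motif(natural, "FDPPPF")
    icosl = max(
        (c for c in natural.chains if c.id != icos.id),
        key=lambda c: len(one_letter_sequence(c.residues)),
    )
    side_icos = select(natural, chains=icos.id, include_hetero=True, label="ICOS")
    side_icosl = select(natural, chains=icosl.id, include_hetero=False, label="ICOS-L")
    imap = buried_surface(natural, side_icos, side_icosl)
    fp_icos, fp_icosl = interface_residues(imap)
    report["natural_complex"] = {
        "icos_bsa": imap.total_a,
        "icosl_bsa": imap.total_b,
        "icos_footprint": len(fp_icos),
        "icosl_footprint": len(fp_icosl),
        "fdpppf_area": region_contribution(
            imap, "A", select(natural, ranges=[(icos.id, 114, 119)])
        ).region_area,
        "tktkgs_area": region_contribution(
            imap, "A", select(natural, ranges=[(icos.id, 66, 71)])
        ).region_area,
        "n_hbonds": len(find_hbonds(natural, select(natural, chains=icos.id, include_hetero=False), side_icosl)),
        "crossing_angle_deg": crossing_angle(
            select(natural, ranges=[(icos.id, 21, 129)], include_hetero=False),
            select(natural, ranges=[(icosl.id, 19, 127)], include_hetero=False),
        ),
    }
    glycan_res = [r for r in side_icos.residues if r.is_hetero]
    if glycan_res:
        imap_gly = buried_surface(natural, Selection(natural, glycan_res, label="glycan"), side_icosl)
        report["natural_complex"]["glycan_burial_on_icosl"] = imap_gly.total_b

    stim = load("7JOO")
    icos_ab = best_match(stim, icos)
    fabs = [c.id for c in stim.chains if c.id != icos_ab.id and len(one_letter_sequence(c.residues)) > 150]
    imap_stim = buried_surface(
        stim,
        select(stim, chains=icos_ab.id, include_hetero=True, label="ICOS"),
        select(stim, chains=fabs, include_hetero=False, label="STIM003"),
    )
    fp_stim, _ = interface_residues(imap_stim)
    mapping = map_residues(icos, icos_ab)
    report["icos_stim003"] = {
        "icos_bsa": imap_stim.total_a,
        "cross_crystal_backbone_rmsd": backbone_rmsd(icos, icos_ab, mapping),
        "n_hbonds": len(find_hbonds(stim, select(stim, chains=icos_ab.id, include_hetero=False),
                                    select(stim, chains=fabs, include_hetero=False))),
        "n_salt_bridges": len(find_salt_bridges(stim, select(stim, chains=icos_ab.id, include_hetero=False),
                                                select(stim, chains=fabs, include_hetero=False))),
        "mimicry_f_icos": mimicry_fraction(fp_icos, fp_stim, mapping, molecule="ICOS").fraction,
    }

    prez = load("6X4T")
    icosl_ab = best_match(prez, icosl)
    fabs = [c.id for c in prez.chains if c.id != icosl_ab.id and 150 < len(one_letter_sequence(c.residues)) < 250]
    imap_prez = buried_surface(
        prez,
        select(prez, chains=icosl_ab.id, include_hetero=True, label="ICOS-L"),
        select(prez, chains=fabs, include_hetero=False, label="prezalumab"),
    )
    fp_prez, _ = interface_residues(imap_prez)
    mapping_l = map_residues(icosl, icosl_ab)
    report["icosl_prezalumab"] = {
        "icosl_bsa": imap_prez.total_a,
        "mimicry_f_icosl": mimicry_fraction(fp_icosl, fp_prez, mapping_l, molecule="ICOS-L").fraction,
    }

    OUT.mkdir(exist_ok=True)
    (OUT / "deposited_structures_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    print(json.dumps(report, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
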