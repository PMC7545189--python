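"""Hydrogen-bond and salt-bridge enumeration against brute-force scans."""

import numpy as np
import pytest

from epimimic.contacts import (
    ContactCriteria,
    find_hbonds,
    find_salt_bridges,
)
from epimimic.structure_io import Atom, Chain, Residue, ResidueID, SelectionError, StructureModel, select


def residue(chain, seq, name, atom_specs):
    atoms = [Atom(n, el, np.asarray(xyz, float)) for n, el, xyz in atom_specs]
    return Residue(ResidueID(chain, seq), name, atoms)


def two_sided(res_a, res_b):
    model = StructureModel(chains=[Chain("A", res_a), Chain("B", res_b)])
    return model, select(model, "A"), select(model, "B")


class TestFindHbonds:
    def test_backbone_pair_within_criteria(self):
        # donor N (with CA antecedent) 2.9 A from acceptor O, angle ~150 deg
        model, sa, sb = two_sided(
            [residue("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (-1.2, -0.8, 0))])],
            [residue("B", 1, "GLY", [("O", "O", (2.68, 1.1, 0))])],  # d = 2.9
        )
        bonds = find_hbonds(model, sa, sb)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=0.01)
        assert bonds[0].angle > 90.0

    def test_distance_cutoff_excludes(self):
        model, sa, sb = two_sided(
            [residue("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (-1.2, -0.8, 0))])],
            [residue("B", 1, "GLY", [("O", "O", (4.2, 0, 0))])],
        )
        assert find_hbonds(model, sa, sb) == []

    def test_angle_criterion_excludes_backfolded(self):
        # acceptor on the same side as the antecedent: angle ~0
        model, sa, sb = two_sided(
            [residue("A", 1, "GLY", [("N", "N", (0, 0, 0)), ("CA", "C", (-1.4, 0, 0))])],
            [residue("B", 1, "GLY", [("O", "O", (-2.9, 0, 1.0))])],
        )
        assert find_hbonds(model, sa, sb) == []

    def test_proline_backbone_n_is_not_donor(self):
        model, sa, sb = two_sided(
            [residue("A", 1, "PRO", [("N", "N", (0, 0, 0)), ("CA", "C", (-1.4, 0, 0))])],
            [residue("B", 1, "GLY", [("O", "O", (2.9, 0, 0))])],
        )
        assert find_hbonds(model, sa, sb) == []

    def test_his_ring_nitrogen_both_donor_and_acceptor(self):
        # protonation is unknown, so His ND1 accepts from Ser OG and donates to it
        model, sa, sb = two_sided(
            [residue("A", 1, "SER", [("OG", "O", (0, 0, 0)), ("CB", "C", (-1.4, 0, 0))])],
            [residue("B", 1, "HIS", [("ND1", "N", (2.8, 0.5, 0))])],
        )
        pairs = {(b.donor.atom, b.acceptor.atom) for b in find_hbonds(model, sa, sb)}
        assert pairs == {("OG", "ND1"), ("ND1", "OG")}

    def test_glycan_hydroxyls_participate(self):
        # sugar O3 donates/accepts; ring O5 may accept but not donate
        sugar = residue("A", 201, "NAG", [("O3", "O", (0, 0, 0)), ("C3", "C", (-1.4, 0, 0))])
        sugar.atoms[0].is_hetero = True
        sugar.atoms[1].is_hetero = True
        partner = residue("B", 1, "GLN", [("NE2", "N", (2.9, 0.3, 0)), ("CD", "C", (4.2, 0.9, 0))])
        model, sa, sb = two_sided([sugar], [partner])
        bonds = find_hbonds(model, sa, sb)
        pairs = {(b.donor.atom, b.acceptor.atom) for b in bonds}
        assert ("NE2", "O3") in pairs  # Gln side chain donates to the hydroxyl
        assert ("O3", "NE2") not in pairs  # NE2 is not an acceptor

    def test_overlapping_sides_rejected(self):
        model, sa, _ = two_sided(
            [residue("A", 1, "GLY", [("N", "N", (0, 0, 0))])],
            [residue("B", 1, "GLY", [("O", "O", (3, 0, 0))])],
        )
        with pytest.raises(SelectionError):
            find_hbonds(model, sa, sa)

    def test_symmetric_in_sides(self):
        model, sa, sb = _random_fixture(seed=0)
        ab = find_hbonds(model, sa, sb)
        ba = find_hbonds(model, sb, sa)
        assert {(b.donor, b.acceptor) for b in ab} == {(b.donor, b.acceptor) for b in ba}

    def test_dmax_monotonicity(self):
        model, sa, sb = _random_fixture(seed=1)
        loose = find_hbonds(model, sa, sb, ContactCriteria(d_max=4.5))
        tight = find_hbonds(model, sa, sb, ContactCriteria(d_max=3.0))
        assert len(loose) >= len(tight)


def _random_fixture(seed: int, n_per_side: int = 25):
    """Two chains of 4-atom residues with random coordinates in a 25 A box:
    200 atoms with plenty of marginal donor/acceptor geometry."""
    rng = np.random.default_rng(seed)
    templates = [
        ("SER", [("OG", "O"), ("CB", "C"), ("N", "N"), ("O", "O")]),
        ("LYS", [("NZ", "N"), ("CE", "C"), ("N", "N"), ("O", "O")]),
        ("ASP", [("OD1", "O"), ("OD2", "O"), ("CG", "C"), ("N", "N")]),
        ("GLU", [("OE1", "O"), ("OE2", "O"), ("CD", "C"), ("N", "N")]),
        ("HIS", [("ND1", "N"), ("NE2", "N"), ("CG", "C"), ("O", "O")]),
        ("ARG", [("NH1", "N"), ("NH2", "N"), ("NE", "N"), ("CZ", "C")]),
    ]

    def make_side(chain_id):
        residues = []
        for i in range(n_per_side):
            name, atom_spec = templates[i % len(templates)]
            center = rng.uniform(0, 25, size=3)
            atoms = [
                (n, el, center + rng.uniform(-1.2, 1.2, size=3)) for n, el in atom_spec
            ]
            residues.append(residue(chain_id, i + 1, name, atoms))
        return residues

    model = StructureModel(chains=[Chain("A", make_side("A")), Chain("B", make_side("B"))])
    return model, select(model, "A"), select(model, "B")


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(5))
    def test_hbond_spatial_search_equals_all_pairs(self, seed):
        model, sa, sb = _random_fixture(seed)
        fast = find_hbonds(model, sa, sb, method="binned")
        brute = find_hbonds(model, sa, sb, method="brute")
        assert [(b.donor, b.acceptor, b.distance) for b in fast] == [
            (b.donor, b.acceptor, b.distance) for b in brute
        ]

    @pytest.mark.parametrize("seed", range(3))
    def test_salt_bridges_equal_naive_residue_scan(self, seed):
        model, sa, sb = _random_fixture(seed)
        found = {
            (b.basic, b.acidic): b.distance for b in find_salt_bridges(model, sa, sb)
        }
        basic_atoms = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
        acidic_atoms = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
        naive = {}
        for basic_side, acidic_side in ((sa, sb), (sb, sa)):
            for rb in basic_side.residues:
                for ra in acidic_side.residues:
                    if rb.name not in basic_atoms or ra.name not in acidic_atoms:
                        continue
                    dists = [
                        np.linalg.norm(rb.get_atom(nb).xyz - ra.get_atom(na).xyz)
                        for nb in basic_atoms[rb.name]
                        for na in acidic_atoms[ra.name]
                        if rb.get_atom(nb) is not None and ra.get_atom(na) is not None
                    ]
                    if dists and min(dists) <= 4.0:
                        naive[(rb.id, ra.id)] = min(dists)
        assert found.keys() == naive.keys()
        for key in found:
            assert found[key] == pytest.approx(naive[key], abs=1e-9)


class TestFindSaltBridges:
    def test_lys_glu_pair_in_range(self):
        model, sa, sb = two_sided(
            [residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0)), ("CE", "C", (-1.4, 0, 0))])],
            [residue("B", 1, "GLU", [("OE1", "O", (3.2, 0, 0)), ("OE2", "O", (4.0, 1.0, 0))])],
        )
        bridges = find_salt_bridges(model, sa, sb)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.2, abs=1e-9)

    def test_out_of_range_pair_excluded(self):
        model, sa, sb = two_sided(
            [residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0))])],
            [residue("B", 1, "GLU", [("OE1", "O", (6.0, 0, 0))])],
        )
        assert find_salt_bridges(model, sa, sb) == []

    def test_two_independent_pairs_counted_once_each(self):
        model, sa, sb = two_sided(
            [
                residue("A", 1, "ARG", [("NH1", "N", (0, 0, 0)), ("NH2", "N", (0.8, 1.0, 0))]),
                residue("A", 2, "ARG", [("NH1", "N", (20, 0, 0))]),
            ],
            [
                residue("B", 1, "ASP", [("OD1", "O", (3.0, 0, 0)), ("OD2", "O", (3.5, 1.2, 0))]),
                residue("B", 2, "ASP", [("OD1", "O", (23.5, 0, 0))]),
            ],
        )
        bridges = find_salt_bridges(model, sa, sb)
        assert len(bridges) == 2
        assert {(b.basic.seqnum, b.acidic.seqnum) for b in bridges} == {(1, 1), (2, 2)}
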