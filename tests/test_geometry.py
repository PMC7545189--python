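"""Kabsch superposition, backbone r.m.s.d., domain axes and crossing angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.optimize import minimize

from epimimic.geometry import (
    DomainAxis,
    GeometryError,
    axis_angle,
    backbone_rmsd,
    crossing_angle,
    principal_axis,
    superpose,
)
from epimimic.structure_io import Selection, StructureModel, map_residues, select
from epimimic.synthetic import (
    ToyComplexSpec,
    make_toy_interface,
    random_rotation,
    rigid_transform_model,
)

from conftest import make_protein_chain


def grid_search_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """Independent oracle: best r.m.s.d. over rotations via coarse Euler grid
    plus local refinement (no SVD)."""
    ref0 = ref - ref.mean(axis=0)
    mob0 = mob - mob.mean(axis=0)

    def rmsd_of(euler: np.ndarray) -> float:
        rot = Rotation.from_euler("zyx", euler).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mob0 @ rot.T - ref0) ** 2, axis=1))))

    grid = np.linspace(-np.pi, np.pi, 13)
    best = min(
        (np.array([a, b, c]) for a in grid for b in grid[:7] for c in grid),
        key=rmsd_of,
    )
    res = minimize(rmsd_of, best, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
    return float(res.fun)


class TestSuperpose:
    def test_identical_coordinates(self):
        coords = np.random.default_rng(0).normal(size=(10, 3))
        result = superpose(coords, coords)
        assert result.rmsd < 1e-12
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_applied_transform(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 3)) * 5
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([1.0, -2.0, 3.0])
        result = superpose(coords, moved)
        assert result.rmsd < 1e-6
        assert np.allclose(result.rotation @ rot, np.eye(3), atol=1e-9)
        assert np.allclose(result.apply(moved), coords, atol=1e-9)

    def test_noisy_fit_beats_prefit_and_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(5, 3)) * 4
        mob = ref @ random_rotation(3).T + rng.normal(scale=0.3, size=(5, 3))
        pre = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
        result = superpose(ref, mob)
        assert result.rmsd <= pre
        assert result.rmsd == pytest.approx(grid_search_rmsd(ref, mob), abs=1e-3)

    def test_proper_rotation_even_for_reflected_input(self):
        coords = np.random.default_rng(2).normal(size=(6, 3))
        reflected = coords * np.array([1.0, 1.0, -1.0])
        result = superpose(coords, reflected)
        assert np.isclose(np.linalg.det(result.rotation), 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(GeometryError, match="at least 3"):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(GeometryError, match="collinear"):
            superpose(line, line)


class TestBackboneRmsd:
    @pytest.fixture
    def chain(self):
        toy = make_toy_interface(ToyComplexSpec(n_residues=8, n_contacts=0, contact_indices=()))
        return toy.model.get_chain("A")

    def test_self_is_zero(self, chain):
        mapping = map_residues(chain, chain)
        assert backbone_rmsd(chain, chain, mapping) < 1e-9

    def test_rigidly_moved_copy_is_zero(self, chain):
        model = StructureModel(chains=[chain])
        moved = rigid_transform_model(model, random_rotation(5), np.array([3.0, 1.0, -7.0]))
        moved_chain = moved.get_chain("A")
        mapping = map_residues(chain, moved_chain)
        assert backbone_rmsd(chain, moved_chain, mapping) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, chain):
        rng = np.random.default_rng(4)
        model = StructureModel(chains=[chain])
        other = rigid_transform_model(model)  # deep copy
        for res in other.get_chain("A").residues:
            for atom in res.atoms:
                atom.xyz = atom.xyz + rng.normal(scale=0.5, size=3)
        mapping = map_residues(chain, other.get_chain("A"))
        base = backbone_rmsd(chain, other.get_chain("A"), mapping)
        moved = rigid_transform_model(other, random_rotation(6), np.array([-4.0, 2.0, 9.0]))
        again = backbone_rmsd(chain, moved.get_chain("A"), mapping)
        assert again == pytest.approx(base, abs=1e-6)

    def test_missing_oxygen_dropped_pairwise(self, chain):
        model = StructureModel(chains=[chain])
        pruned = rigid_transform_model(model)
        last = pruned.get_chain("A").residues[-1]
        last.atoms = [a for a in last.atoms if a.name != "O"]
        mapping = map_residues(chain, pruned.get_chain("A"))
        assert backbone_rmsd(chain, pruned.get_chain("A"), mapping) == pytest.approx(0.0, abs=1e-9)


class TestDomainAxes:
    def _line_selection(self, reverse=False):
        chain = make_protein_chain("AAAAAA")
        residues = chain.residues[::-1] if reverse else chain.residues
        model = StructureModel(chains=[chain])
        return Selection(model, list(residues))

    def test_straight_line_axis(self):
        axis = principal_axis(self._line_selection())
        assert np.allclose(axis.direction, [1.0, 0.0, 0.0], atol=1e-9)

    def test_terminus_order_flips_sign(self):
        axis = principal_axis(self._line_selection(reverse=True))
        assert np.allclose(axis.direction, [-1.0, 0.0, 0.0], atol=1e-9)

    def test_helical_coil_recovers_generating_axis(self):
        from epimimic.structure_io import Atom, Chain, Residue, ResidueID

        rng = np.random.default_rng(8)
        axis_dir = np.array([1.0, 2.0, 2.0]) / 3.0
        rot = Rotation.align_vectors([axis_dir], [[0.0, 0.0, 1.0]])[0].as_matrix()
        residues = []
        for i in range(20):
            local = np.array([2.3 * np.cos(i), 2.3 * np.sin(i), 1.5 * i])
            xyz = rot @ local + rng.normal(scale=0.05, size=3)
            residues.append(Residue(ResidueID("H", i + 1), "ALA", [Atom("CA", "C", xyz)]))
        model = StructureModel(chains=[Chain("H", residues)])
        axis = principal_axis(Selection(model, residues))
        angle = np.degrees(np.arccos(np.clip(abs(np.dot(axis.direction, axis_dir)), -1, 1)))
        assert angle < 5.0

    def test_too_few_ca_rejected(self):
        chain = make_protein_chain("AAA")
        model = StructureModel(chains=[chain])
        with pytest.raises(GeometryError, match="CA"):
            principal_axis(Selection(model, chain.residues))


class TestAxisAngle:
    e = lambda self, v: DomainAxis(centroid=np.zeros(3), direction=np.asarray(v, float))

    @pytest.mark.parametrize(
        "v1,v2,expected",
        [
            ([1, 0, 0], [1, 0, 0], 0.0),
            ([1, 0, 0], [0, 1, 0], 90.0),
            ([1, 0, 0], [-1, 0, 0], 180.0),
        ],
    )
    def test_reference_angles(self, v1, v2, expected):
        assert axis_angle(self.e(v1), self.e(v2)) == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            v1, v2 = rng.normal(size=(2, 3))
            a1 = self.e(v1 / np.linalg.norm(v1))
            a2 = self.e(v2 / np.linalg.norm(v2))
            assert axis_angle(a1, a2) == pytest.approx(axis_angle(a2, a1), abs=1e-12)

    def test_crossing_angle_rigid_invariance(self):
        toy = make_toy_interface(ToyComplexSpec(n_residues=8, n_contacts=3))
        sel_a = select(toy.model, "A")
        sel_b = select(toy.model, "B")
        base = crossing_angle(sel_a, sel_b)
        moved = rigid_transform_model(toy.model, random_rotation(10), np.array([2.0, 4.0, -6.0]))
        again = crossing_angle(select(moved, "A"), select(moved, "B"))
        assert again == pytest.approx(base, abs=1e-6)
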