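"""Synthetic fixtures with analytically known truth.

Everything downstream is testable offline through these generators:

* two-sphere systems whose SASA/BSA follow the closed-form spherical-cap
  expressions (the oracle for the Shrake-Rupley engine);
* toy two-chain complexes where exactly k designated residue pairs are
  within burial distance, so footprint sizes are known by construction;
* paired "natural" and "antibody" toy complexes sharing a known number of
  contacted residues on a common target chain, so the mimicry fraction has
  an exact truth n_shared / n_interface;
* multi-concentration 1:1 Langmuir sensorgrams bundled with their generating
  parameters for recovery tests.

All generators are deterministic given their seed.  Toy residues carry a
minimal N, CA, C, O, CB atom set with ideal-geometry placement: enough for
SASA, backbone r.m.s.d. and hydrogen-bond donor/acceptor typing without a
rotamer library.  Chains are laid out with an exaggerated 11 A residue
spacing so that a partner residue at contact distance buries only its
directly opposite residue — that spacing, not physics, is what makes the
footprint truth exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from epimimic.kinetics import KineticModel, Sensorgram, dilution_series, simulate_sensorgram
from epimimic.sasa import SasaParams
from epimimic.structure_io import Atom, Chain, Residue, ResidueID, StructureModel

__all__ = [
    "two_sphere_model",
    "two_sphere_reference",
    "ToyComplexSpec",
    "ToyInterface",
    "make_toy_interface",
    "MimicryScenario",
    "make_mimicry_pair",
    "make_bli_dataset",
    "rigid_transform_model",
    "random_rotation",
]


# ---------------------------------------------------------------------------
# two-sphere analytic system


def two_sphere_model(
    r1: float, r2: float, d: float, probe: float = 1.4, n_points: int = 960
) -> tuple[StructureModel, SasaParams]:
    """Two single-atom chains at separation d, with radii r1 and r2.

    The atoms use element symbols C and N with a custom radius table bundled
    in the returned :class:`SasaParams`, so arbitrary radii can be exercised.
    """
    if min(r1, r2, d) < 0 or r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive and separation non-negative")
    atom_a = Atom(name="X1", element="C", xyz=np.zeros(3), is_hetero=True)
    atom_b = Atom(name="X2", element="N", xyz=np.array([d, 0.0, 0.0]), is_hetero=True)
    model = StructureModel(
        chains=[
            Chain("A", [Residue(ResidueID("A", 1), "UNK", [atom_a])]),
            Chain("B", [Residue(ResidueID("B", 1), "UNK", [atom_b])]),
        ]
    )
    params = SasaParams(probe_radius=probe, n_points=n_points, radii={"C": r1, "N": r2})
    return model, params


def two_sphere_reference(r1: float, r2: float, d: float, probe: float = 1.4) -> dict[str, float]:
    """Closed-form SASA/BSA of the two-sphere system.

    With expanded radii R_i = r_i + probe, the accessible area of sphere 1 is
    its full area 4*pi*R1^2 minus the spherical cap hidden inside sphere 2.
    The cap height follows from the lens geometry: the intersection plane
    sits at x1 = (d^2 + R1^2 - R2^2) / (2 d) from centre 1, so
    h1 = R1 - x1 and the hidden area is 2*pi*R1*h1 (and symmetrically for
    sphere 2).  BSA per sphere equals its hidden cap area.
    """
    big1 = 4.0 * np.pi * (r1 + probe) ** 2
    big2 = 4.0 * np.pi * (r2 + probe) ** 2
    rr1, rr2 = r1 + probe, r2 + probe
    if d >= rr1 + rr2:  # disjoint
        return {"sasa_a": big1, "sasa_b": big2, "bsa_a": 0.0, "bsa_b": 0.0}
    if d == 0.0 and rr1 == rr2:  # coincident identical spheres: mutual full burial
        return {"sasa_a": 0.0, "sasa_b": 0.0, "bsa_a": big1, "bsa_b": big2}
    if d <= abs(rr1 - rr2):  # one sphere inside the other
        if rr1 < rr2:
            return {"sasa_a": 0.0, "sasa_b": big2, "bsa_a": big1, "bsa_b": 0.0}
        return {"sasa_a": big1, "sasa_b": 0.0, "bsa_a": 0.0, "bsa_b": big2}
    x1 = (d * d + rr1 * rr1 - rr2 * rr2) / (2.0 * d)
    h1 = rr1 - x1
    h2 = rr2 - (d - x1)
    hidden1 = 2.0 * np.pi * rr1 * h1
    hidden2 = 2.0 * np.pi * rr2 * h2
    return {
        "sasa_a": big1 - hidden1,
        "sasa_b": big2 - hidden2,
        "bsa_a": hidden1,
        "bsa_b": hidden2,
    }


# ---------------------------------------------------------------------------
# toy residue/chain builders

# ideal local geometry relative to CA, partner side along +y
_LOCAL_ATOMS = {
    "N": np.array([-1.46, 0.00, 0.0]),
    "CA": np.array([0.00, 0.00, 0.0]),
    "C": np.array([1.52, 0.00, 0.0]),
    "O": np.array([2.05, 1.11, 0.0]),
    "CB": np.array([0.00, 1.53, 0.0]),
}
_EXTENT = 3.51  # max atom-x spread inside a residue (N to O)
_MAX_REACH = 2.0 * (1.80 + 1.4)  # two expanded carbons: largest occluding pair distance


def _toy_residue(rid: ResidueID, ca: np.ndarray, flip_y: bool, rng: np.random.Generator) -> Residue:
    atoms = []
    for name, offset in _LOCAL_ATOMS.items():
        off = offset.copy()
        if flip_y:
            off[1] = -off[1]
        jitter = rng.uniform(-0.03, 0.03, size=3)
        atoms.append(Atom(name=name, element=name[0], xyz=ca + off + jitter))
    return Residue(rid, "ALA", atoms)


@dataclass(frozen=True)
class ToyComplexSpec:
    """Two poly-alanine-like strands with designated contacting residue pairs."""

    n_residues: int = 10
    n_contacts: int = 4
    contact_indices: tuple[int, ...] | None = None
    contact_gap: float = 7.0  # CA-CA gap across the interface at contact sites, A
    far_gap: float = 30.0
    spacing: float = 11.0  # along-strand CA-CA spacing, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_gap <= 0 or self.far_gap <= self.contact_gap:
            raise ValueError("need 0 < contact_gap < far_gap")
        if self.far_gap - 2 * _LOCAL_ATOMS["CB"][1] <= _MAX_REACH:
            raise ValueError("far_gap too small: non-contact residues would still bury area")
        if self.spacing - _EXTENT <= _MAX_REACH:
            raise ValueError("spacing too small: contacts would leak onto neighbouring residues")
        idx = self.resolved_contacts()
        if any(i < 0 or i >= self.n_residues for i in idx):
            raise ValueError("contact indices out of range")

    def resolved_contacts(self) -> tuple[int, ...]:
        if self.contact_indices is not None:
            return tuple(sorted(set(self.contact_indices)))
        return tuple(range(self.n_contacts))


@dataclass
class ToyInterface:
    model: StructureModel
    chain_a: str
    chain_b: str
    contact_indices: tuple[int, ...]

    @property
    def expected_footprint(self) -> tuple[int, int]:
        k = len(self.contact_indices)
        return (k, k)


def _build_chain_pair(
    n_residues: int,
    contacts_b: set[int],
    contact_gap: float,
    far_gap: float,
    spacing: float,
    rng: np.random.Generator,
    chain_a_id: str = "A",
    chain_b_id: str = "B",
    start_seqnum_b: int = 1,
) -> tuple[Chain, Chain]:
    res_a, res_b = [], []
    for i in range(n_residues):
        ca_a = np.array([i * spacing, 0.0, 0.0])
        res_a.append(_toy_residue(ResidueID(chain_a_id, i + 1), ca_a, flip_y=False, rng=rng))
        gap = contact_gap if i in contacts_b else far_gap
        ca_b = np.array([i * spacing, gap, 0.0])
        res_b.append(
            _toy_residue(ResidueID(chain_b_id, start_seqnum_b + i), ca_b, flip_y=True, rng=rng)
        )
    return Chain(chain_a_id, res_a), Chain(chain_b_id, res_b)


def make_toy_interface(spec: ToyComplexSpec) -> ToyInterface:
    """Two-chain complex in which exactly the designated residues touch.

    At a contact site the opposing CB atoms sit ~4 A apart (well inside
    occlusion range), while the 11 A strand spacing keeps every other
    cross-chain atom pair beyond the largest possible occlusion distance, so
    footprint sizes are (k, k) by construction at any tau up to a few A^2.
    """
    rng = np.random.default_rng(spec.seed)
    contacts = set(spec.resolved_contacts())
    chain_a, chain_b = _build_chain_pair(
        spec.n_residues, contacts, spec.contact_gap, spec.far_gap, spec.spacing, rng
    )
    model = StructureModel(chains=[chain_a, chain_b])
    return ToyInterface(model=model, chain_a="A", chain_b="B", contact_indices=tuple(sorted(contacts)))


# ---------------------------------------------------------------------------
# mimicry scenario


@dataclass
class MimicryScenario:
    natural_model: StructureModel
    antibody_model: StructureModel
    target_chain: str
    natural_partner: str
    antibody_partner: str
    n_interface: int
    n_shared: int

    @property
    def truth_fraction(self) -> float:
        return self.n_shared / self.n_interface


def make_mimicry_pair(n_interface: int, n_shared: int, seed: int = 0) -> MimicryScenario:
    """Natural and antibody toy complexes with an exact shared-footprint truth.

    The target chain T is byte-identical in both complexes (same sequence and
    coordinates, so residue correspondence is the identity).  Its natural
    partner L contacts residues 1..n_interface; the antibody chain H contacts
    the first n_shared of those plus two padding residues beyond the natural
    interface (antibody-only contacts, which belong in no denominator).
    Truth: f = n_shared / n_interface.
    """
    if n_interface < 1:
        raise ValueError("n_interface must be >= 1")
    if not 0 <= n_shared <= n_interface:
        raise ValueError("need 0 <= n_shared <= n_interface")

    n_extra = 2  # antibody-only contact sites outside the natural footprint
    n_res = n_interface + n_extra + 2
    natural_contacts = set(range(n_interface))
    antibody_contacts = set(range(n_shared)) | {n_interface, n_interface + 1}

    rng_t = np.random.default_rng(seed)
    target_res = [
        _toy_residue(ResidueID("T", i + 1), np.array([i * 11.0, 0.0, 0.0]), False, rng_t)
        for i in range(n_res)
    ]

    def _partner(chain_id: str, contacts: set[int], rng: np.random.Generator) -> Chain:
        residues = []
        for i in range(n_res):
            gap = 7.0 if i in contacts else 30.0
            ca = np.array([i * 11.0, gap, 0.0])
            residues.append(_toy_residue(ResidueID(chain_id, i + 1), ca, True, rng))
        return Chain(chain_id, residues)

    def _clone_target() -> Chain:
        return Chain(
            "T",
            [
                Residue(r.id, r.name, [Atom(a.name, a.element, a.xyz.copy()) for a in r.atoms])
                for r in target_res
            ],
        )

    natural = StructureModel(
        chains=[_clone_target(), _partner("L", natural_contacts, np.random.default_rng(seed + 1))]
    )
    antibody = StructureModel(
        chains=[_clone_target(), _partner("H", antibody_contacts, np.random.default_rng(seed + 2))]
    )
    return MimicryScenario(
        natural_model=natural,
        antibody_model=antibody,
        target_chain="T",
        natural_partner="L",
        antibody_partner="H",
        n_interface=n_interface,
        n_shared=n_shared,
    )


# ---------------------------------------------------------------------------
# BLI datasets


def make_bli_dataset(
    truth: KineticModel | None = None,
    concentrations: list[float] | None = None,
    t_assoc: float = 180.0,
    t_dissoc: float = 180.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[Sensorgram, KineticModel]:
    """Sensorgram plus its generating truth, under the standard assay design:
    180 s association/dissociation phases and a six-point 1:2 serial dilution
    from 500 nM unless overridden."""
    truth = truth or KineticModel(kon=2.2e5, koff=1.6e-1, rmax=1.0)
    concentrations = concentrations if concentrations is not None else dilution_series(500e-9, 6)
    data = simulate_sensorgram(
        truth, concentrations, t_assoc=t_assoc, t_dissoc=t_dissoc, dt=dt, noise_sd=noise_sd, seed=seed
    )
    return data, truth


# ---------------------------------------------------------------------------
# rigid-motion helpers (for invariance checks and fixture variation)


def random_rotation(seed: int = 0) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform_model(
    model: StructureModel,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    chains: set[str] | None = None,
) -> StructureModel:
    """Copy of a model with x -> R x + t applied (optionally to given chains)."""
    rot = np.eye(3) if rotation is None else np.asarray(rotation, float)
    trans = np.zeros(3) if translation is None else np.asarray(translation, float)
    new_chains = []
    for ch in model.chains:
        residues = []
        for res in ch:
            atoms = []
            for a in res.atoms:
                xyz = a.xyz.copy()
                if chains is None or ch.id in chains:
                    xyz = rot @ xyz + trans
                atoms.append(
                    Atom(a.name, a.element, xyz, a.occupancy, a.altloc, a.bfactor, a.is_hetero)
                )
            residues.append(Residue(res.id, res.name, atoms))
        new_chains.append(Chain(ch.id, residues))
    return StructureModel(chains=new_chains, accession=model.accession)
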