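# Methods

## Structure model

All geometry runs on a small hierarchical container (model → chain →
residue → atom) populated from PDB or mmCIF text via gemmi.  Three
normalisations happen at load time and nowhere else:

* **waters dropped** — no water-mediated contact is ever reported, so waters
  would only perturb SASA;
* **hydrogens dropped** — the crystal structures this targets (2.4–3.3 Å)
  carry none, and every criterion in the package is heavy-atom based;
* **alternate conformers collapsed** — per atom name the highest-occupancy
  conformer is kept, ties resolved in favour of altloc `A`, so downstream
  geometry is single-conformer and deterministic.

Author (deposited) residue numbering is authoritative throughout: it is how
interface residues are named (e.g. F114, N110) and how ranges are selected.
Hetero residues (glycans, ions) are first-class; a glycan covalently linked
to a chain is included in that chain's side of an interface unless excluded
explicitly, because glycan atoms can carry a real share of the buried
surface.

Residue correspondence across crystal forms uses global Needleman–Wunsch
alignment with identity scoring (match 1, mismatch 0, gap open −10, extend
−0.5; biopython's `PairwiseAligner` as the engine).  Identity scoring is
enough because the mapped chains are near-identical copies of the same
molecule; the stiff gap penalty keeps the mapping collinear.

## SASA (Shrake–Rupley)

Per-atom SASA uses `n_points` quasi-uniform points per atom from a
golden-section spiral — deterministic, so repeated runs are bit-identical —
on the expanded sphere of radius `r_atom + probe`.  A point is accessible
iff it lies strictly outside every neighbour's expanded sphere (a relative
epsilon of 1e−9 treats points exactly on a neighbour's surface as buried,
which only matters for degenerate coincident-sphere fixtures).  Area is the
accessible fraction times `4π(r+probe)²`.

Defaults: probe 1.4 Å, 960 points, and a NACCESS/Chothia-style per-element
radius table (C 1.80, N 1.65, O 1.40, S 1.85 Å; saccharide C/O share the
protein values).  Published buried-surface figures for this system were
produced with PISA, whose internal parameterisation is not published; a
documented single-radius-per-element table was chosen for reproducibility,
and comparisons against published BSA totals carry a ±15% tolerance to
absorb the parameterisation difference.

Neighbour search is spatial binning with cell size `2·(r_max + probe)`,
contractually identical to the all-pairs scan (`method="brute"` exposes the
scan; a test asserts bitwise equality).  Accuracy at the defaults: an
isolated atom's SASA is exact to < 0.5%, and on the two-sphere system the
numeric BSA tracks the closed-form spherical-cap value to < 0.5% of the
sphere area across separations.

A derivation note on the two-sphere oracle: with expanded radii R₁, R₂ at
separation d, the intersection plane sits at `x₁ = (d² + R₁² − R₂²)/(2d)`
from centre 1, the hidden cap has height `h₁ = R₁ − x₁` and area `2πR₁h₁`.
The hidden cap of the **smaller** sphere shrinks monotonically from full
burial to zero as d grows; the larger sphere's cap vanishes at *both* ends
of the lens range (a fully contained small sphere hides nothing on the big
one), so only the smaller sphere's BSA is monotone in d — the property the
tests assert.

## Buried surface area and footprints

BSA is computed per side from three SASA evaluations with identical
parameters: side A alone, side B alone, and the union.  Per-atom BSA is the
drop in SASA on complex formation; with a shared deterministic point set it
is non-negative by construction.  The two per-side totals are reported
separately (the per-ectodomain convention); PISA's halved "interface area"
convention is not used.

A footprint is the set of residues with BSA **strictly** above τ; τ = 1 Å²
everywhere by default, taken from the definition of the mimicry statistic.
Region contributions (e.g. a loop motif's share of a side's footprint) are
sums of per-residue BSA over a selection, reported with the fraction of the
side total; regions partitioning a side sum to the side total exactly.

## Mimicry fraction

For a molecule with natural-complex footprint N and antibody-complex
footprint A (both at the same τ, residues matched by alignment):

    f = |{r ∈ N : map(r) ∈ A}| / |N|

Natural-footprint residues with no counterpart in the antibody crystal form
stay in the denominator — unmodelled residues must not inflate the score.
The antibody side uses the same BSA > τ rule as the natural side: the
statistic's definition states the threshold only for the natural footprint,
and symmetry is the cleanest reading.  f is invariant to rigid motion of
either structure and is *not* claimed monotone in τ (raising τ can remove
residues from numerator and denominator in either order).

## Geometry

Superposition is the Kabsch least-squares fit via SVD with determinant
correction (always a proper rotation); near-collinear point sets are
rejected as ill-posed.  Backbone r.m.s.d. is computed over mapped
N/CA/C/O pairs after optimal superposition, dropping atoms missing on
either side pairwise (terminal O atoms are commonly absent).

A domain axis is the first principal component of the domain's Cα cloud,
sign-fixed so it points N→C (dot product with C-terminal-Cα minus
N-terminal-Cα non-negative).  The crossing angle between two domains is the
angle between their oriented axes over the full [0, 180]° range; the N→C
convention is what makes ~150° distinguishable from ~30°.  The published
analysis used a PyMOL recipe whose definition is unstated; this deterministic
definition recovers generated angles on synthetic coils to < 0.2° and is
compared to published angles with a ±10° tolerance.

## Contacts

Hydrogen bonds: donor/acceptor heavy-atom pairs across the interface with
distance ≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 90° (antecedent = a
covalently bonded heavy atom of the donor's residue, bond cutoff 1.8 Å; if
several antecedents exist the most favourable angle is used, and an
antecedent-free donor — only possible in abstract fixtures — passes without
an angle check).  Donors: any N except proline's backbone N; Ser/Thr/Tyr
hydroxyl O; saccharide hydroxyl O (ring O5 and the N-acetyl carbonyl O7
excluded).  Acceptors: any O plus His ND1/NE2.  His is deliberately both
donor and acceptor (protonation unknown at these resolutions), so a
His-N/hydroxyl-O pair can contribute one bond in each direction.

Salt bridges: Lys NZ / Arg NE,NH1,NH2 versus Asp OD1,OD2 / Glu OE1,OE2,
minimum inter-group distance ≤ 4.0 Å, one bridge per residue pair.

These unpublished-criteria defaults are standard low-resolution practice;
published counts are matched within ±2.  The fast search (scipy cKDTree)
is pinned by test to agree with the all-pairs scan bitwise.

## Kinetics

1:1 Langmuir model: association `R(t) = R_eq(1 − e^{−k_obs t})` with
`k_obs = k_on C + k_off`, `R_eq = R_max C/(C + K_D)`; dissociation is a
single exponential at rate `k_off`.  `K_D` is the identity `k_off/k_on`,
never a free parameter.  Simulation adds i.i.d. Gaussian noise from a
seeded generator (numpy PCG64), so every stochastic test is reproducible.

Fitting is global nonlinear least squares over all concentrations with
shared (k_on, k_off, R_max), optimised in log-parameter space
(Levenberg–Marquardt), initialised from a log-linear dissociation fit
(k_off) followed by a k_obs-vs-C regression (k_on).  Standard errors come
from the Gauss–Newton covariance of the log-parameters (delta method for
K_D).  Non-identifiable designs — fewer than two concentrations, a span
below 4-fold, or no dissociation phase — return a flagged result rather
than raising.  Under the standard design (180 s phases, six-point 1:2
dilution from 500 nM, 2% noise) median recovery error is ~2–3% for k_on and
~2% for k_off over 100 noise realisations.

The bivalent-analyte mode models two sequential attachment steps with a
cross-linking rate `k₂` (units 1/(nm·s)) on free surface `S = R_max − R₁ − 2R₂`:

    dR₁/dt = 2·k_on·C·S − k_off·R₁ − k₂·R₁·S + 2·k_off·R₂
    dR₂/dt = k₂·R₁·S − 2·k_off·R₂,     response = R₁ + R₂

integrated with LSODA.  With k₂ = 0 this reduces analytically to 1:1 with
doubled k_on (two free arms), which a test verifies.  The default k₂ = 10
corresponds to efficient rebinding on a densely loaded sensor and makes the
apparent 1:1 K_D roughly two orders of magnitude tighter than the intrinsic
per-site K_D — the observed contrast between monomeric and dimeric analyte
orientations.  The mode exists to demonstrate that contrast; it is never
fitted to data.

## Synthetic systems — what they do and do not show

The generators build: (a) two-sphere systems with closed-form SASA/BSA;
(b) toy two-chain complexes of minimal-atom residues (N, CA, C, O, CB at
ideal local geometry) where an exaggerated 11 Å residue spacing guarantees
that a partner residue at contact distance (7 Å CA–CA gap) buries exactly
its opposite residue and nothing else — footprint sizes are therefore exact
construction truths; (c) mimicry pairs sharing a byte-identical target
chain so the residue mapping is the identity and f has an exact truth; (d)
sensorgrams from known parameters.  All are deterministic given their seed,
and generated PDB text re-parses losslessly.

What passing these tests shows: the SASA integration, footprint logic,
alignment plumbing, contact search, fitting machinery and the statistic
itself are correct against independent truth.  What they do not show: real
interfaces are dense and irregular — footprints there depend on the radius
table and τ in ways the toy systems cannot probe, which is exactly why the
published-value checks on the deposited structures carry the generous
tolerances above and why the toy spacing is not physical.

## Problem sizes

The default test and analysis runs use toy complexes of ≤ 100 atoms,
two-sphere grids of ~10–25 separations, 100 noise realisations for kinetic
recovery, and 960 sphere points per atom — sizes chosen so the full chain
of evidence (analytic oracle → primitive → pipeline statistic) runs in
seconds while leaving the sampling fine enough that the analytic
comparisons are meaningful.  The deposited-structure analyses (thousands of
atoms) run in minutes and are gated only on the one-time fetch.

## Known limitations

* Per-element radii cannot reproduce PISA's context-dependent radii
  exactly; published-BSA comparisons are tolerance-based.
* No Lee–Richards variant, no polar/apolar decomposition, no interface
  energetics or shape complementarity.
* Contact typing has no π-stacking/cation-π detection and no hydrogen
  placement.
* The bivalent model is a two-step serial approximation (no lateral
  rebinding kinetics, no mass transport).
* Crossing angles depend on the domain selections supplied; the package
  never guesses domain boundaries.
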