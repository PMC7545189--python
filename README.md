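# epimimic

Structural analysis of receptor/ligand interfaces and of how closely
therapeutic antibodies mimic them, with companion 1:1 biosensor kinetics.

## The problem

Immune checkpoint receptors such as ICOS (on T cells) engage their ligands
(ICOS-L on antigen-presenting cells) through a small set of interface
residues — for ICOS, a proline-rich FDPPPF loop plus a TKTKGS stretch in
strand C′, and even an N-linked glycan at N110.  Blocking antibodies in
clinical development (STIM003 against ICOS, prezalumab against ICOS-L) work
by occupying that same surface.  Quantifying *how much* of the natural
footprint an antibody covers requires a reproducible chain of structural
primitives, which this package provides:

* **SASA** — per-atom solvent-accessible surface area by the Shrake–Rupley
  method (deterministic golden-spiral sampling, per-element radii);
* **BSA** — per-side buried surface area of a binary interface,
  `BSA = SASA(side alone) − SASA(side in complex)`;
* **footprints** — residues with BSA > τ (τ = 1 Å² by default);
* **mimicry fraction** — for a molecule with natural footprint *N* and
  antibody-complex footprint *A* (residues matched across crystal forms by
  sequence alignment), `f = |{r ∈ N : map(r) ∈ A}| / |N|`;
* **geometry** — Kabsch superposition, backbone r.m.s.d., principal-axis
  domain directions and the crossing (approach) angle between IgV domains;
* **contacts** — hydrogen bonds and salt bridges under explicit heavy-atom
  criteria (d ≤ 3.5 Å, antecedent–donor–acceptor angle ≥ 90°; salt bridges
  at ≤ 4.0 Å), glycan hydroxyls included;
* **kinetics** — 1:1 Langmuir sensorgram simulation and global fitting
  (`R(t) = R_eq(1 − e^{−(k_on C + k_off)t})`, dissociation `e^{−k_off t}`,
  `K_D ≡ k_off/k_on`), plus a bivalent-analyte mode that reproduces the
  avidity contrast between monomeric and dimeric analytes.

Every stage is testable offline against synthetic systems with analytic or
constructed truth (two-sphere spherical-cap oracle, toy interfaces with a
known number of contacting residues, mimicry pairs with a known shared
fraction, sensorgrams with known rate constants).

## Worked example

```python
import epimimic as em
from epimimic import synthetic as syn

# a natural complex and an antibody complex sharing target chain T:
# 4 interface residues, 3 of them also contacted by the antibody
scenario = syn.make_mimicry_pair(n_interface=4, n_shared=3, seed=0)

nat, ab = scenario.natural_model, scenario.antibody_model
imap_nat = em.buried_surface(nat, em.select(nat, "T"), em.select(nat, "L"))
imap_ab = em.buried_surface(ab, em.select(ab, "T"), em.select(ab, "H"))
fp_nat, _ = em.interface_residues(imap_nat, tau=1.0)
fp_ab, _ = em.interface_residues(imap_ab, tau=1.0)
mapping = em.map_residues(nat.get_chain("T"), ab.get_chain("T"))
score = em.mimicry_fraction(fp_nat, fp_ab, mapping)
print(f"f = {score.fraction}  ({score.n_contacted}/{score.n_interface} residues)")
```

prints

```
f = 0.75  (3/4 residues)
```

three of the four residues the natural partner buries (> 1 Å²) are also
buried by the antibody, so the antibody covers 75% of the natural footprint.

The kinetics side (`analysis/07_kinetics_recovery.py`) simulates the
standard assay design — 180 s phases, six-point 1:2 dilution from 500 nM,
2% noise — and prints:

```
converged fits: 100/100
median recovery errors (%):
kon_err    2.79
koff_err   1.69
kd_err     1.76

intrinsic per-site KD: 727 nM
apparent 1:1 KD of the bivalent analyte: 11.1 nM
avidity tightening: 65x
```

i.e. the global fit recovers the generating rate constants to ~2%, and a
bivalent analyte fitted with a 1:1 model appears ~65× tighter than its
intrinsic per-site affinity — the signature of avidity.

## Layout

* `src/epimimic/` — the library (structure I/O, SASA, interface, geometry,
  contacts, mimicry, kinetics, synthetic generators, pipeline, CLI).
* `analysis/01…08_*.py` — numbered narrative drivers; each runs one stage on
  the synthetic systems (08 on the deposited structures, network-gated) and
  writes its tables under `results/`.
* `epimimic` CLI — `analyze-interface`, `mimicry`, `angles`, `contacts`,
  `simulate-bli`, `fit-bli`, `make-fixtures`, `fetch`.

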