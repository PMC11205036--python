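# Methods

## Scope and model

`mgrna` annotates divalent-magnesium binding sites in RNA-containing
crystal structures and estimates their binding affinity with an additive
per-contact free-energy model. The analysis has four stages:

1. **Contact detection.** Mg²⁺ is octahedrally coordinated with a
   crystallographic Mg–O bond near 2.07 Å. Every non-carbon,
   non-phosphorus, non-metal heteroatom (O, N, halides, S/Se) within the
   inner-sphere cutoff of the metal is a first-shell ligand; first-shell
   waters are collected separately. Each first-shell water is then
   scanned for hydrogen-bond partners among RNA/ligand heteroatoms
   within a distance window; each such partner is one water-mediated
   *outer-sphere* contact. Crystal structures generally lack hydrogens,
   so hydrogen bonds are recognised by donor–acceptor distance alone —
   no angular criterion, and no donor/acceptor role assignment.
2. **Geometry classification.** The non-water inner ligand set is
   labelled with the coordination-isomer vocabulary (cis, trans, fac,
   mer; mono for a single ligand) from its pairwise ligand–Mg–ligand
   angles.
3. **Motif classification.** Inner phosphate oxygens from
   sequence-adjacent nucleotides of one chain form a 10-membered chelate
   ring pair. Two pairs make a magnesium clamp; one pair plus a distant
   (sequence separation ≥ 2) or other-chain phosphate makes a Y-clamp;
   one pair alone is a plain 10-membered ring. Sites whose contacts
   span two or more chains are flagged `packing_suspect`.
4. **Scoring.** ΔG_b = n_IS·(−3.3) + n_OS·(−1.2) kcal/mol, with waters
   themselves contributing nothing. The total maps to a functional-role
   class (see below).

The model deliberately ignores everything the per-contact energies
cannot resolve: ligand-class-specific inner-sphere energies, steric and
electrostatic penalty terms (not separately measurable), ion–ion
repulsion, and fractional site occupancy. Occupancy is reported but
never used to filter sites.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `inner_cutoff` | 2.6 | Å | Mg–O ≈ 2.07 Å; 2.6 tolerates refinement error, excludes the ~4.2 Å second shell |
| `hbond_min`, `hbond_max` | 2.4, 3.5 | Å | conventional heavy-atom hydrogen-bond window |
| `angle_tolerance` | 30 | degrees | chelate rings distort ideal 90°/180° octahedral angles |
| `dg_inner` | −3.3 | kcal/mol | experimental per-contact inner-sphere value |
| `dg_outer` | −1.2 | kcal/mol | experimental per-contact outer-sphere value |
| `role_bounds` | −13.2, −9.0 | kcal/mol | see below |

Role boundaries: sites with ΔG_b above −9.0 kcal/mol are classed
`charge_neutralization` (weak, largely outer-sphere ions balancing
backbone charge); the ~−10 kcal/mol region is the `transition` regime
where minimal inner-sphere and compensatory outer-sphere modes coexist;
`structural` begins at −13.2 kcal/mol — the energy of four inner-sphere
phosphates, i.e. the two chelate pairs of a magnesium clamp. The −9.0
boundary is an experimental observation; the −13.2 boundary is this
package's convention (configurable), chosen so that every clamp-class
motif scores structural. A site at exactly −9.0 falls in `transition`
(the charge-neutralization class is a strict inequality).

Energies are carried as exact decimal numbers in tenths of kcal/mol
(`decimal.Decimal`), so tabulated totals reproduce bit-exactly and never
accumulate binary floating-point error.

## Detection rules worth knowing

* O5′/O3′ bridging oxygens count as phosphate-class; O2′/O4′ as
  ribose-class; the standard base ring/exocyclic N and O set as
  base-class. A residue with a non-standard name is still a nucleotide
  if it carries a full phosphate group (P, OP1, OP2) and a ribose atom;
  all other hetero groups (e.g. a bound F⁻) are exogenous. Exogenous
  inner contacts score exactly like phosphate contacts — the additive
  model has a single inner-sphere value.
* An RNA atom reachable through two bridging waters is counted once,
  keeping the shortest bridge: the model counts unique ligand atoms per
  class, not water pathways.
* One nucleotide may contribute both an inner and an outer contact to
  the same ion; each is counted.
* Altloc conformers resolve to the highest occupancy (ties:
  lexicographically smaller altloc id). Only the first model of a
  multi-model file is used.
* No crystallographic symmetry expansion is performed. Inter-chain
  bridges are *flagged*, not reconstructed or discarded: without
  symmetry-operator bookkeeping a biological inter-chain bridge cannot
  be distinguished from a packing mate, and packing-stabilised sites
  are unlikely to survive in solution, so the flag marks the site for
  user review and no functional role should be read into it.
* With two or more ring pairs the clamp label takes precedence over the
  (overlapping) multi-pair reading of the 10-membered-ring class; the
  pair list is always reported so either reading can be applied. A
  phosphate adjacent to two possible partners is paired greedily by
  ascending combined Mg distance (logged).

## The synthetic-fixture generator

Real deposited structures are deliberately not required for testing.
The generator builds idealised scenes: Mg at the origin, first-shell
oxygens at 2.07 Å on octahedral axes, second-shell acceptors at 2.8 Å
from their bridging water — both ≥ 0.3 Å inside the detection windows —
with residue numbering and chains arranged per motif template. The
octahedral fill order places consecutive ligands cis, so a chelate pair
sits at 90°, four phosphates span the equatorial plane, and an
exogenous axial ligand lands on ±z.

**Noise model.** Each fixture receives a random rigid rotation and
translation, and every non-metal atom is jittered along its direction
from the Mg by a zero-mean Gaussian of the requested standard deviation
(default 0; the shipped example fixtures use 0.02 Å, a typical
coordinate-precision scale for well-refined structures). Radial jitter
perturbs every detection-relevant distance while leaving
ligand–Mg–ligand angles exact. This is a deliberate design choice: the
generator's purpose is labelled ground truth, and isotropic noise of
realistic magnitude would — with small but non-negligible probability —
tilt a pair angle across a tight classification window and silently
falsify the label. Under radial noise the angular labels are exact by
construction and the distance margins are the only thing at stake.

Consequently, a green stability test establishes robustness of the
*distance* thresholds (and of everything downstream of the detected
topology) to coordinate noise, and establishes angular-window behaviour
only at the ideal angles. It does not establish robustness to angular
distortion of real chelate rings — that is what the generous 30°
default tolerance is for — nor does the generator emulate real backbone
stereochemistry, crowded crystal environments, altloc disorder, or
partial occupancy. Parser behaviour for those cases is exercised by
hand-written PDB fragments instead.

The three shipped example recipes (`example_site_specs`) are synthetic
stand-ins reproducing the contact topology — not the coordinates — of
three well-characterised binding modes: a fluoride-riboswitch-type site
(4 phosphates in two chelate pairs + axial F⁻; ΔG_b = −16.5), a
glycine-riboswitch-type inter-chain site (2 phosphates + 1 ribose
inner, 3 outer base contacts; −13.5, packing-suspect), and a
ribozyme-type outer-sphere site (1 inner phosphate, 6 water-mediated
contacts; −10.5).

## Numerical and degenerate-input choices

* Angles are computed as arccos of clipped normalised dot products;
  contacts are sorted by (distance, chain, residue, atom name) so output
  is deterministic even under exact distance ties.
* Geometry classification windows: cis = [90−tol, 90+tol], trans =
  [180−tol, 180]. For four ligands, two disjoint trans pairs (the planar
  arrangement) label the site trans; note that four exactly coplanar
  octahedral directions always contain two trans pairs, so the
  "four mutually cis" branch is reachable only for non-octahedral
  inputs. Tolerances above ~45° make the cis and trans windows overlap
  and the labels lose meaning; the tested range is 5–45°.
* A site with zero non-water inner ligands has no geometry label
  (raising is preferred over a sentinel); the pipeline records it as
  empty and still scores the outer sphere.
* More than six first-shell ligands triggers a warning, not an error —
  refinement artifacts should be visible, not hidden.
* The production neighbour search is a k-d tree over ligand-eligible
  heteroatoms; the test suite holds it to *exact* agreement with an
  all-pairs O(n²) scan.

## Known limitations

* Inner/outer assignment is purely distance-based; strained or
  misrefined sites near the window edges will flip categories with the
  cutoffs. All windows are exposed as parameters.
* The single per-contact energies make all inner contacts equivalent;
  the ordering of sites is robust to this, absolute totals less so.
* Chain-crossing detection flags biological inter-chain bridges too —
  the flag means "review", not "artifact".
* Sequence adjacency is author-numbering-based; a chelate pair spanning
  a renumbering discontinuity or insertion codes will not be paired.
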