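# Methods

This note documents the models and numerical choices behind foldkit's four
analyses, the parameters that matter, what the synthetic fixture generator
does and does not emulate, and the known limitations.

## Structure normalization

PDB input is parsed with gemmi and reduced to a single normalized atom
table: only the first MODEL of a multi-model (NMR) file is used; within an
altloc group only the first state of each atom is kept; waters are dropped;
non-water HETATM ligands are dropped by default (selenomethionine is
treated as methionine, with SE renamed to SD). Residue numbering and
insertion codes are taken verbatim from the file, so author numbering (e.g.
a "Ser 75" in a 74-residue chain) is preserved. Hydrogens present in the
input are retained.

Van der Waals radii (Å): C 1.88, N 1.64, O 1.42, S 1.77, H 1.0, default
1.8 for anything else (with a logged warning); water probe 1.4. The carbon
radius is pinned by the published carbon–carbon candidate cutoff:
2 × (1.88 + 1.4) = 6.56 Å. All radii are overridable via `RadiusTable`.

## Contact areas (CSU section algorithm)

For every heavy atom A of the selected residues, the solvent-extended
sphere (radius r_A + 1.4 Å) is discretized into `n_sections` (default 610)
equal-area directions from a golden-angle Fibonacci lattice. For each
section, a probe at P = c_A + (r_A + probe)·u is tested against every
candidate neighbor B — heavy atoms of *other* residues with
|c_A − c_B| ≤ (r_A + probe) + (r_B + probe), found through a k-d tree. The
section belongs to the claimant whose center is closest to c_A (ties broken
by lower atom serial; the iteration claims sections in closest-first order,
which implements exactly that rule). Each owned section contributes
4π(r_A + probe)²/n to the (residue(A), residue(B)) cell; the reported
matrix is the symmetrized sum of the two directed totals.

Numerical choices:

- **Area sphere.** Section areas are measured on the solvent-extended
  sphere (the sphere the sections actually live on), not the bare vdW
  sphere. Both conventions are implemented
  (`ContactParams.area_sphere`) since published cluster areas do not state
  which is used; the solvent-extended form is the default on the grounds of
  internal consistency. Bare-vdW areas are smaller by (r_A/(r_A+probe))².
- **Occluders.** All heavy atoms of the structure compete for sections
  (physical occlusion) but only selection–selection pairs accumulate area;
  `occluder_scope="selection-only"` restricts competition to the selection.
- **Rotational invariance.** A space-fixed lattice would make areas change
  by ±1–2 sections under rigid rotation of the coordinates. Each atom's
  lattice is therefore expressed in a molecule-anchored frame (z toward the
  nearest candidate neighbor, x toward the first non-collinear one, serial
  tie-breaks), which makes the matrix exactly invariant under rigid
  transforms while staying fully deterministic.
- **Resolution.** The default 610 sections reproduce single-neighbor
  analytic cap areas to ≲ 1% at separations 3–6 Å, but a near-cutoff
  contact (6.5 Å for C–C) subtends only ~2 sections, where quantization
  error reaches tens of percent of a sub-Å² area. Tests that compare
  against Monte-Carlo/analytic oracles at such separations therefore refine
  the grid (n = 6100 resolves the full 3.0–6.5 Å sweep to ≤ 0.9%); the
  refinement invariant (610 vs 6100 within 5% on ordinary geometries)
  covers default-grid adequacy separately.
- Intra-residue contacts are excluded outright (an atom's own residue
  neither claims nor receives sections), giving a zero-diagonal residue
  matrix. Hydrogens never participate.

## ILV hydrophobic clusters

Residue pairs from {ILE, LEU, VAL} (configurable) with symmetrized contact
area ≥ 10 Å² form edges; clusters are connected components with at least
two members (singletons are not reported), ordered by descending total
area. A cluster's total area sums each member pair's contact area once;
both "area per contact" (total/contacts — the statistic historically
labeled *area per residue* in the web-server lineage this reimplements) and
the literal total/size are reported, so no ambiguity is hidden. All heavy
atoms of ILV residues participate by default, backbone included; a
sidechain-only flag exists.

## Hydrogen-bond networks

Protonation uses fixed pH-7 states with deterministic geometric placement —
no pKa estimation and no sidechain flipping. Sites: Ser/Thr/Tyr hydroxyls
(1 H, O–H 0.96 Å; torsion scanned in 10° steps and pointed at the nearest
N/O acceptor within 3.5 Å, else staggered anti to the grandparent atom),
Lys NZ (3 H, tetrahedral, staggered), Arg NE/NH1/NH2 (5 H, planar
guanidinium), Asn/Gln amides (2 H, planar), Trp NE1 (1 H), His (neutral;
single tautomer on ND1 or NE2, chosen to maximize potential hydrogen-bond
partners within 3.5 Å of the protonated nitrogen, ties to NE2), Asp/Glu
carboxylates none. N–H bonds are 1.01 Å. Pre-existing hydrogens are kept
and their donors are not re-protonated, so an externally protonated file
(e.g. from a pKa-aware pipeline) bypasses internal placement entirely.
Residues with missing sidechain heavy atoms are skipped with a warning.

Detection: every hydrogen is paired with its covalent N/O donor (nearest
within 1.3 Å); acceptors are all N/O atoms. A bond requires d(H···A) < 2.5 Å
and donor–H–acceptor angle > 120°, donor and acceptor in different
residues; the default scope requires both to be sidechain atoms. The bond
set is cross-checked in the test suite against mdtraj's `baker_hubbard`
(same criterion) on identical coordinates. Networks are connected
components of the residue graph (one edge per residue pair regardless of
bond multiplicity), ordered by size then residue number.

Because protonation here is geometric rather than pKa-based, marginal bonds
can differ from pipelines that titrate sidechains or flip amides; network
counts on real structures should be read with that ±1 sensitivity in mind.

## Salt bridges and charge metrics

Salt bridges: all Asp OD1/OD2 and Glu OE1/OE2 oxygens against all Lys NZ
and Arg NE/NH1/NH2 nitrogens, distance strictly below 4.0 Å, computed on
heavy-atom positions (no hydrogens, no charge centroids). Histidine is
excluded by default, consistent with its neutral pH-7 treatment elsewhere
in the toolkit (`include_his=True` adds ND1/NE2); chain termini can be
added with `include_termini=True`. Networks are residue-graph components.

Charge metrics operate on the one-letter sequence (for structures: parsed
residues in file order). Charges: K, R +1; D, E −1; everything else
including histidine 0 (`his_positive=True` flips that). δ_g uses
overlapping windows, step 1. δ_max is computed **exactly** — enumerating
every distinct charge arrangement, vectorized — whenever the composition
has at most 10⁵ arrangements (this covers every sequence of length ≤ 10
and all sparse-charge compositions); beyond that, the maximum over a
segregated candidate family: each charge sign in one contiguous block, the
neutral residues split into up to three runs around them (all splits,
coarsened to ≤ 41 positions per axis for very neutral compositions), both
block orders. Exhaustive checks show that fully blocked arrangements alone
are *not* always optimal — sequences barely longer than the blob can peak
at arrangements with charges at both termini — which is why the exhaustive
path extends as far as it does and why the candidate family is wider than
the naive three-block set. κ is the mean of δ_g/δ_max,g for g ∈ {5, 6},
NaN when the sequence carries no charge (and necessarily for 6-mers, whose
single g = 6 window makes δ₆ ≡ 0). Terminal charges are ignored.

## Contact maps

Entry (i, j) is the minimum distance over heavy-atom pairs of residues i
and j (hydrogens optional), diagonal forced to zero. Raw distances are
reported; a thresholded 0/1 export is available but no cutoff is applied by
default.

## Synthetic fixtures

The fixture generator builds PDB text from idealized residue geometry
(chemical-component-dictionary templates bundled with biotite): residue
pairs whose closest heavy atoms sit at an exact separation (solved by root
finding on the translation), explicit donor–H···acceptor triples with exact
d and ϑ, chains of residues along an axis with optional seeded jitter, and
degenerate decorations (altloc duplicates, a second model, HETATM water)
for parser tests. Fixtures are geometric unit-test scaffolds: they exercise
cutoffs, ownership rules, protonation geometry and graph logic exactly, but
they are not folded proteins — they contain steric clashes and no secondary
structure, so passing tests demonstrate algorithmic correctness, not
biophysical realism on real structures. The two published worked examples
(PDB 2LN3 and 2M71) complement them when network access is available to
fetch the coordinates; those checks validate end-to-end numbers on real
NMR structures.

## Problem sizes used in the standard runs

The bundled verification runs use: a 4 × 10⁵–8 × 10⁶-direction Monte-Carlo
probe oracle per separation (sample sizes chosen to hold sampling noise
near 0.5%), 500 random 100-node graphs for partition equivalence, 10⁴
random sequences of length 20–80 for the κ bound, all ~470 charge
compositions of length ≤ 10 for brute-force δ_max equivalence, and
50-residue synthetic chains for contact-map oracles.

## Known limitations

- No pKa estimation, no His/Asn/Gln flip optimization, and no
  occupancy-aware altloc handling; protonation-sensitive hydrogen-bond
  networks can differ from pKa-aware pipelines by a network or two.
- mmCIF input is not supported (PDB text only).
- δ_max beyond the exhaustive regime is a lower bound from the candidate
  family; κ could in principle marginally exceed values normalized by the
  true maximum, though no violation of κ ≤ 1 appears in 10⁴ random
  sequences.
- Contact areas are the section approximation by construction; no analytic
  sphere-intersection areas are computed.
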