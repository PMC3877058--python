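# Methods

`pockalign` superposes two protein ligand-binding pockets by rigid-body
search over voxelized surface representations and scores the overlay by
how much of the query pocket surface is matched — without using sequence
or fold information, so that pockets of entirely unrelated proteins can be
compared. This note documents the model, the parameters that matter, the
numerical choices, and what the synthetic test data does and does not
establish.

## Pipeline

**1. Structure preparation** (`structure_io`). PDB files are parsed with
gemmi; only MODEL 1 and the first alternate location per atom name are
kept. Every atom is classified as protein, reference ligand, water or
other heteroatom. The reference ligand is the HETATM group named by the
selector, or the largest non-water HETATM group. Ligand molecular weight
is the sum of standard atomic masses of the atoms present in the record —
no implicit hydrogens are added, since HETATM records usually lack them,
and the 300–800 g/mol library window is applied to this heavy-atom-
dominated mass. Waters are discarded by default; `retain-near` keeps
water atoms within 5 Å of any ligand atom, a deliberately simple
point-distance stand-in for retaining ordered binding-site waters (no
protonation or interaction-energy model is attempted).

**2. Surface membership** (`surface_model`). The pipeline needs only the
*set* of atoms that touch the solvent-excluded surface (SES), not the
surface mesh. An atom is SES-contributing when a probe sphere (radius
1.4 Å, water) can be placed tangent to it without overlapping any other
atom, tested over 256 quasi-uniform directions (golden-spiral lattice);
atoms that fail this but can be touched by a probe resting simultaneously
on two accessible neighbours (sampled on the bitangent circle, 32 points)
are re-entrant contributors and are also included. Bondi-style van der
Waals radii are used (C 1.70, N 1.55, O 1.52, S/P 1.80, H 1.20, halogens
per table); unknown elements fall back to 1.70 Å with a logged warning.
At the 1 Å grid resolution used downstream, this sampled membership test
is equivalent in practice to an analytical SES computation; on convex
clusters it coincides exactly with the set of atoms with positive
solvent-accessible area (checked against an independent Shrake–Rupley
implementation in the tests).

**3. Pocket detection** (`pocket_model`). Candidate pocket spheres are
lattice points (1 Å spacing) in the ligand's neighbourhood (ligand
bounding box expanded by 8 Å) that (a) lie above the SES — outside every
atom's vdW + probe envelope — and (b) are deeply buried, with at least 45
protein heavy atoms within 8 Å. The burial pair (45, 8 Å) was fixed on
fixtures such that a concave cavity fills with spheres while a flat face
does not; both are exposed as parameters. Spheres are sorted by distance
to the ligand's geometric centre (ties broken lexicographically by
coordinates); the nearest is accepted and the sorted list is re-scanned
to closure, accepting any sphere strictly within 1.5 Å of an accepted
one. Running to a fixpoint rather than a single sweep keeps curved
channels connected regardless of whether distance-to-centre is monotone
along the pocket. Spheres are treated as centre points (zero radius)
throughout. The tight bounding box of the accepted centres is the pocket
box; SES atoms strictly within 4 Å of the pocket box or of the ligand
bounding box (Euclidean distance to the solid box, 0 inside) form the
relevant pocket surface.

**4. Grids** (`grid_builder`). Surface atoms and spheres are voxelized at
1 Å resolution using cell-centre classification with precedence
surface > pocket > above-surface > elsewhere: surface if strictly within
1.8 Å of a surface atom, pocket if strictly within 1.8 Å of a sphere
centre, above-surface in the 1 Å shell just beyond the surface band
(strictly within 2.8 Å of a surface atom). Cell values are
{surface: +1, above_surface: +0.5, pocket: −1, elsewhere: 0} — the
minimal assignment for which the product-sum correlation rewards
surface-on-surface and pocket-on-pocket overlap and penalises placing
surface into pocket volume; the above-surface half-weight acts as a soft
tolerance shell. Only the location of the correlation maximum matters
downstream, which the sign structure pins; all four values are
configurable.

**5. Superposition search** (`superposer`). The template is rotated over
the full Euler lattice — α, β, γ ∈ {0°, 20°, …, 340°}, 5832 samples,
applied as R = Rz(γ)·Ry(β)·Rx(α) about the centroid of the template's
pocket spheres — and re-gridded after each rotation (points are rotated
and voxelized afresh; the grid is never resampled, avoiding interpolation
artifacts). For each rotation, the correlation with the query grid over
*all* integer translations is obtained at once as
IFT(conj(DFT(f))·DFT(g)), the classical FFT correlation trick from
rigid-body docking, here applied to pocket overlays. Both grids are
zero-padded to a common box of at least dim_f + dim_g per axis (rounded
to an FFT-friendly size), so the reported argmax cannot be a wrap-around
alias. The global argmax over rotations and shifts is selected with
strict `>` comparisons in fixed lexicographic (α, β, γ, x₀, y₀, z₀)
order — no epsilon, machine-stable ties. The batched FFT scan runs in
single precision; the winning correlation is then recomputed in double
precision as the direct product sum, and that value is reported. The
cyclic shift is unwrapped to a signed shift and combined with the two
grid origins into a real-space rigid transform mapping template
coordinates into the query frame. Note that the ZYX Euler lattice is not
closed under matrix inversion, so ground-truth transforms in the recovery
tests are drawn as inverses of lattice rotations — the search then has an
exactly representable answer; because the parametrization double-covers
parts of SO(3), an equivalent rotation with different Euler angles may be
reported, which the tests accept by comparing mapped coordinates rather
than angles.

**6. Scoring** (`similarity_score`). With the transform applied to the
template's pocket-surface atoms, ms counts query surface atoms having at
least one template surface atom strictly within 1.8 Å, and ops counts
query sphere centres having one strictly within 1.4 Å (template protein
obscuring the query pocket volume). The score is

    score = ms / N_surf − ops / N_sph ∈ [−1, 1],

the fraction of query surface matched minus the normalized obscured-
pocket penalty; the two term weights are configurable and default to 1.
A perfect self-overlay scores exactly 1; a completely disjoint placement
scores 0. The Cα ablation rebuilds both pocket models from only the Cα
atoms of surface-contributing residues, searches without pocket spheres
in the grids, and scores the result in the normal way (query spheres are
retained for the ops term) — quantifying how much the all-atom surface
description contributes over a backbone-only one.

**7. Screening** (`screen`). Each library template is compared to the
query by global sequence identity (Needleman–Wunsch, BLOSUM62, gap open
10 / extend 0.5; identity = identical aligned positions / alignment
length including gaps — conventional parameters; the 40%/60% filters are
coarse enough that reasonable choices agree) and secondary-structure
identity (fraction of aligned non-gap residue pairs with equal 3-state
class, 8-state DSSP collapsed as {H,G,I}→H, {E,B}→E, else C). Templates
strictly above either cutoff (40% sequence, 60% secondary structure) are
excluded — the point of the tool is *distant* off-targets — and the
survivors are superposed, scored and ranked by descending score with
deterministic tie-breaks. DSSP strings can be supplied externally; the
built-in assigner is a simplified Kabsch–Sander implementation
(electrostatic H-bond energy with the standard 0.084·332 coupling, bond
if E < −0.5 kcal/mol, amide H reconstructed from the preceding peptide
unit; two consecutive i→i+4 turns mark a helix, parallel/antiparallel
bridge patterns mark strands). It reproduces a reference DSSP
implementation on ideal fixtures but is an approximation on irregular
real chains; identity filters for production screens should prefer real
DSSP output.

**8. Evaluation** (`evaluation`). Ranked lists are turned into ROC
problems by one of two labeling schemes: *ligand-centered* (a protein is
a true off-target when the query structure's co-crystallized ligand binds
it strictly below 10 µM) or *target-centered* (it shares at least half of
the target's sub-µM inhibitors; the denominator is the target's inhibitor
set by default, with |S_p|, min and union selectable, since "their" is
ambiguous in prose descriptions of such schemes). Proteins without an
affinity record for the relevant compound are excluded rather than
labeled inactive — affinity panels are sparse in general, and silent
negatives would bias the AUC; a `missing-as-negative` switch restores the
alternative. AUC is the Mann–Whitney probability that a random positive
outscores a random negative, ties counted ½ (average ranks).

## Synthetic fixtures

`fixtures.make_cavity_protein` builds a jittered cubic lattice of carbon
atoms filling a ball, with a spherical cavity carved at the surface
(centred at (shell − cavity)·direction, so the cavity breaches the
surface) and a small rigid "ligand" cluster placed inside it. Each atom
is its own single-Cα residue with a seeded random amino-acid type, so
unrelated fixtures have realistically low sequence identity while
transformed copies have identity 1. All randomness is fixed by the seed;
the same spec yields a byte-identical PDB. Unit tests use the compact
geometry (shell 12 Å, cavity 4 Å, spacing 3.0 Å); recovery and
acceptance runs use shell 12 Å, cavity 4.5 Å, spacing 2.6 Å, where the
denser packing makes pocket detection stable under rigid motion of the
whole structure (the candidate-sphere lattice and probe directions are
axis-aligned in space, so re-detection in a rotated frame can otherwise
flip borderline spheres and surface atoms). These sizes keep one full
5832-rotation search near half a minute on one CPU while leaving
realistic detection noise in place.

Because every fixture residue is a single Cα atom, the Cα ablation on a
fixture pair reduces to the full model minus the pocket spheres in the
matching grids; on exact-copy pairs both searches find the same optimum
and the two scores coincide. The large full-versus-Cα score gap the
method exhibits on real distant pocket pairs arises from side-chain
surface detail that these fixtures do not model.

What the fixtures do *not* emulate: covalent geometry and chemistry
(everything is carbon), side chains, multiple chains, partial pocket
matches, conformational flexibility, and crystallographic artifacts.
Passing the recovery and ranking tests therefore demonstrates the
geometric and algorithmic correctness of the pipeline — exact FFT
correlation, argmax recovery of known rigid motions, correct filter and
score semantics — not predictive performance on real proteins, which
depends on data the package does not bundle.

## Degenerate inputs and numerical conventions

Empty protein, missing ligand, no surviving buried spheres, empty pocket
surface, zero query surface atoms or spheres at scoring time, empty
sequences, and single-class label sets all raise typed errors rather than
returning sentinel values. Distances at exactly a threshold are *not*
inside it (strict `<` everywhere: 1.5, 1.8, 1.4, 4 Å); identity filters
exclude strictly above 40%/60%; the affinity label is strictly below
10 µM; the target-centered share is inclusive (≥ half). Grid cells are
half-open boxes classified by centre; the grid origin is the data's min
corner minus the padding, so translating all inputs by whole cells shifts
the origin and leaves the value array bit-identical. Box distances are
Euclidean distances to the solid box. The argmax uses exact comparisons
in a fixed iteration order, so repeated runs are bit-identical.

## Known limitations

- The rotation lattice is coarse (20°); off-lattice poses are recovered
  only to lattice precision, and no local refinement is applied — the
  search stops at the lattice optimum by design.
- SES membership is sampled (256 directions); atoms whose only probe
  access is through gaps smaller than the angular sampling can be
  misclassified. This has no observed effect at 1 Å grid resolution.
- The burial criterion (45 atoms / 8 Å) was fixed on synthetic fixtures;
  very shallow or very wide real pockets may need the exposed parameters
  adjusted.
- The simplified secondary-structure assigner handles single chains
  without chain breaks; supply external DSSP strings for anything else.
- Ligand molecular weight ignores implicit hydrogens, so the library MW
  window is effectively a heavy-atom window.
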