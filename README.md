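# pockalign

Rigid superposition and similarity scoring of protein ligand-binding
pocket surfaces, for finding **distant off-targets**: proteins whose
binding pockets closely resemble a drug target's pocket even though the
two proteins share no significant sequence or fold similarity. Such pairs
are invisible to sequence search and to backbone/pseudo-center pocket
comparison methods, because those rely on exactly the similarity that is
absent — so `pockalign` compares the pocket *surfaces* directly.

## Method

Given a co-crystal structure, the pocket is characterized in three steps:

1. **Pocket extent.** Spheres are placed on a 1 Å lattice at positions
   above the solvent-excluded surface (SES) that are deeply buried in the
   protein; starting from the sphere nearest the reference ligand's
   centre, spheres strictly within 1.5 Å of an accepted sphere are added
   until closure. The bounding box of the accepted spheres defines the
   pocket size.
2. **Relevant surface atoms.** SES-contributing atoms (probe radius
   1.4 Å) strictly within 4 Å of the pocket box or the ligand box.
3. **Signed grid.** Atoms and spheres are voxelized at 1 Å resolution:
   cells within 1.8 Å of a surface atom take value +1, the 1 Å shell
   directly above the surface +0.5, cells within 1.8 Å of a pocket
   sphere −1, elsewhere 0.

Two pockets (query grid *f*, template grid *g*) are superposed by
maximizing the correlation

  c(x₀, y₀, z₀; α, β, γ) = Σ f(l, m, n) · g(l + x₀, m + y₀, n + z₀)

over all translations and all rotations on a 20° Euler lattice
(R = R_z(γ)·R_y(β)·R_x(α), 5832 samples). For each rotation the template
is re-gridded and the correlation over *every* translation is computed at
once via FFTs, c = IFT(conj(DFT f) · DFT g) — the Katchalski-Katzir
trick from protein docking, repurposed for pocket overlays. The sign
structure of the grid values makes surface-on-surface and
pocket-on-pocket overlap attractive and surface-into-pocket placement
repulsive.

The best overlay is scored as

  score = ms / N_surf − ops / N_sph ∈ [−1, 1]

where *ms* is the number of query surface atoms with a template pocket
surface atom strictly within 1.8 Å, and *ops* ("obscured pocket spheres")
the number of query pocket spheres with a template surface atom strictly
within 1.4 Å. A library of template pockets is ranked by this score; for
distant off-target searches, templates with sequence identity > 40% or
3-state secondary-structure identity > 60% (after global alignment) are
excluded first. Ranked lists can be evaluated as ROC problems against an
affinity panel, with ligand-centered (query ligand binds below 10 µM) or
target-centered (shares ≥ half of the target's nanomolar inhibitors)
labeling.

See `docs/methods.md` for parameters, numerical conventions and
limitations.

## Worked example

Generate a synthetic cavity "protein", make a rigidly moved copy, and
superpose the two pockets (a coarser 40° lattice keeps the demo fast;
drop `--angle-step` for the full 20° search):

```sh
pockalign make-fixture query.pdb --seed 11 --cavity-radius 4.5 \
    --spacing 2.6 --ligand-atoms 4
pockalign make-fixture template.pdb --seed 11 --cavity-radius 4.5 \
    --spacing 2.6 --ligand-atoms 4 --rotate 0,0,60 --translate 2,-1,3
pockalign superpose query.pdb template.pdb --angle-step 40
```

```json
{
  "rotation": {"alpha": 0.0, "beta": 0.0, "gamma": 40.0},
  "shift_cells": [0, 0, 0],
  "correlation": 1162.25,
  "score": {"ms": 40, "ops": 0, "n_surf": 41, "n_sph": 56,
            "score": 0.975609756097561}
}
```

Here the template was the query rotated by −60° about z and translated;
the search recovered the nearest lattice rotation (γ = 40° on the 40°
lattice) and an overlay in which 40 of the 41 query pocket-surface atoms
are matched by template surface atoms (*ms*/*N_surf* = 0.976) and none of
the 56 query pocket spheres is obscured by template protein (*ops* = 0),
giving score ≈ 0.976 out of a maximal 1.0.

Other subcommands: `pockalign search` ranks a manifest of template PDBs
against a query and writes a TSV; `pockalign eval` joins a ranking with
an affinity table (TSV: protein_id, compound_id, affinity_molar) and
reports the ROC AUC.

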