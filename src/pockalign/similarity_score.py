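"""Similarity scoring of a pocket superposition.

score = ms / N_surf − ops / N_sph, where ms counts query surface atoms
with at least one transformed template pocket-surface atom strictly within
1.8 Å, and ops ("obscured pocket spheres") counts query pocket-sphere
centres with a transformed template surface atom strictly within 1.4 Å.
The first term is the fraction of query surface matched to template
surface; the second penalises query pocket volume obscured by template
protein.  Both term weights are configurable (defaults 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import UndefinedScoreError
from .pocket_model import PocketModel
from .superposer import (RigidTransform, SuperpositionResult,
                         find_best_superposition)

MS_THRESHOLD = 1.8   # Å, strict <
OPS_THRESHOLD = 1.4  # Å, strict <


@dataclass
class SimilarityScore:
    """Matched-surface and obscured-pocket counts with the final score."""

    ms: int
    ops: int
    n_surf: int
    n_sph: int
    score: float

    def as_dict(self) -> dict:
        return {"ms": self.ms, "ops": self.ops, "n_surf": self.n_surf,
                "n_sph": self.n_sph, "score": self.score}


def score_superposition(query: PocketModel,
                        template: PocketModel,
                        transform: RigidTransform,
                        ms_threshold: float = MS_THRESHOLD,
                        ops_threshold: float = OPS_THRESHOLD,
                        surface_weight: float = 1.0,
                        pocket_weight: float = 1.0) -> SimilarityScore:
    """Score an overlay given the template→query rigid transform."""
    n_surf, n_sph = query.n_surf, query.n_sph
    if n_surf == 0 or n_sph == 0:
        raise UndefinedScoreError(
            f"score undefined: n_surf={n_surf}, n_sph={n_sph}")
    if template.n_surf == 0:
        raise UndefinedScoreError("template has no surface atoms")

    t_surf = transform.apply(template.surface_coords)
    tree = cKDTree(t_surf)

    d_surf, _ = tree.query(query.surface_coords)
    ms = int(np.sum(d_surf < ms_threshold))
    d_sph, _ = tree.query(np.asarray(query.sphere_centers, float).reshape(-1, 3))
    ops = int(np.sum(d_sph < ops_threshold))

    score = surface_weight * ms / n_surf - pocket_weight * ops / n_sph
    return SimilarityScore(ms=ms, ops=ops, n_surf=n_surf, n_sph=n_sph,
                           score=float(score))


def _calpha_reduced(pocket: PocketModel, keep_spheres: bool) -> PocketModel:
    """Pocket model rebuilt from the Cα atoms of surface-contributing residues."""
    if pocket.structure is None:
        raise UndefinedScoreError("Cα ablation needs the parent structure")
    residues = {(a.chain, a.residue_seq) for a in pocket.surface_atoms}
    calphas = [a for a in pocket.structure.atoms
               if a.record_class == "protein" and a.name.strip() == "CA"
               and (a.chain, a.residue_seq) in residues]
    if not calphas:
        raise UndefinedScoreError("no Cα atoms among surface residues")
    spheres = (np.asarray(pocket.sphere_centers, float)
               if keep_spheres else np.zeros((0, 3)))
    coords = np.vstack([a.pos for a in calphas])
    return PocketModel(sphere_centers=spheres,
                       pocket_box=pocket.pocket_box,
                       ligand_box=pocket.ligand_box,
                       surface_atoms=list(calphas),
                       structure=pocket.structure)


def score_calpha_ablation(query: PocketModel, template: PocketModel,
                          angle_step: float = 20.0,
                          ) -> tuple[SimilarityScore, SuperpositionResult]:
    """Superpose and score using only Cα atoms of the surface residues.

    The matching grids contain no pocket spheres; the query spheres are
    retained for the obscured-pocket term so the overlay is scored in the
    normal way.  Returns (score, superposition).
    """
    q_red = _calpha_reduced(query, keep_spheres=False)
    t_red = _calpha_reduced(template, keep_spheres=False)
    # rotate about the template Cα centroid (no spheres in the grids)
    result = find_best_superposition(q_red, t_red, angle_step=angle_step)
    q_scored = PocketModel(sphere_centers=np.asarray(query.sphere_centers, float),
                           pocket_box=query.pocket_box,
                           ligand_box=query.ligand_box,
                           surface_atoms=q_red.surface_atoms,
                           structure=query.structure)
    score = score_superposition(q_scored, t_red, result.transform)
    return score, result
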