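"""Binding-pocket detection by buried-sphere growth.

Candidate points on a 1 Å lattice around the reference ligand are kept when
they sit above the solvent-excluded surface (outside every atom's vdW+probe
envelope) yet are deeply buried (many protein heavy atoms within 8 Å).
Starting from the candidate nearest the ligand's geometric centre, points
are accepted while they lie within 1.5 Å (strictly) of an already accepted
point, run to closure.  The tight bounding box of the accepted sphere
centres defines the pocket extent; SES-contributing atoms within 4 Å of the
pocket box or of the ligand bounding box form the relevant pocket surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyPocketSurfaceError, PocketDetectionError
from .structure_io import AtomRecord, Structure
from .surface_model import (DEFAULT_PROBE_RADIUS, SurfaceAtomSet,
                            ses_contributing_atoms, vdw_radius)

logger = logging.getLogger(__name__)

DEFAULT_BURIAL_MIN = 45       # protein heavy atoms within burial radius
DEFAULT_BURIAL_RADIUS = 8.0   # Å
DEFAULT_LATTICE = 1.0         # Å candidate spacing
DEFAULT_LINKAGE = 1.5         # Å sphere-to-sphere growth distance (strict <)
DEFAULT_BOX_MARGIN = 4.0      # Å atom-to-box extraction distance (strict <)
LIGAND_NEIGHBORHOOD = 8.0     # Å expansion of the ligand box for candidates


def bounding_box(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tight axis-aligned bounding box (min-corner, max-corner)."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("bounding box of empty point set")
    return pts.min(axis=0), pts.max(axis=0)


def box_distance(points: np.ndarray, box: tuple[np.ndarray, np.ndarray]
                 ) -> np.ndarray:
    """Euclidean distance from each point to the solid box (0 inside)."""
    lo, hi = box
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.maximum(np.maximum(lo - pts, pts - hi), 0.0)
    return np.linalg.norm(d, axis=1)


@dataclass
class PocketModel:
    """Accepted pocket spheres, bounding boxes and relevant surface atoms."""

    sphere_centers: np.ndarray              # (k, 3) Å
    pocket_box: tuple[np.ndarray, np.ndarray]
    ligand_box: tuple[np.ndarray, np.ndarray]
    surface_atoms: list[AtomRecord] = field(default_factory=list)
    structure: Optional[Structure] = None   # parent (for Cα ablation)

    @property
    def n_sph(self) -> int:
        return len(self.sphere_centers)

    @property
    def n_surf(self) -> int:
        return len(self.surface_atoms)

    @property
    def surface_coords(self) -> np.ndarray:
        if not self.surface_atoms:
            return np.zeros((0, 3))
        return np.vstack([a.pos for a in self.surface_atoms])

    @property
    def sphere_centroid(self) -> np.ndarray:
        if self.n_sph:
            return self.sphere_centers.mean(axis=0)
        return self.surface_coords.mean(axis=0)


def place_buried_spheres(structure: Structure,
                         surface: SurfaceAtomSet,
                         burial_min: int = DEFAULT_BURIAL_MIN,
                         burial_radius: float = DEFAULT_BURIAL_RADIUS,
                         lattice: float = DEFAULT_LATTICE,
                         probe_radius: float = DEFAULT_PROBE_RADIUS,
                         ) -> np.ndarray:
    """Candidate pocket-sphere centres on a lattice around the ligand.

    A lattice point survives when (a) it lies outside every atom's
    vdW+probe envelope (above the SES) and (b) at least ``burial_min``
    protein heavy atoms lie within ``burial_radius`` of it.  Returns a
    (k, 3) array, possibly empty.
    """
    ligand = structure.ligand_atoms
    if not ligand:
        raise PocketDetectionError(f"{structure.id}: no reference ligand")
    lig_lo, lig_hi = bounding_box(structure.coords(ligand))
    lo = lig_lo - LIGAND_NEIGHBORHOOD
    hi = lig_hi + LIGAND_NEIGHBORHOOD
    axes = [np.arange(lo[d], hi[d] + 0.5 * lattice, lattice) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    occluders = [a for a in structure.atoms
                 if a.record_class in ("protein", "water")]
    occ_coords = np.vstack([a.pos for a in occluders])
    occ_radii = np.array([vdw_radius(a.element) for a in occluders])
    occ_tree = cKDTree(occ_coords)

    heavy = [a for a in structure.protein_atoms if a.element.upper() != "H"]
    heavy_tree = cKDTree(np.vstack([a.pos for a in heavy]))

    keep = np.zeros(len(grid), dtype=bool)
    max_reach = occ_radii.max() + probe_radius
    counts = heavy_tree.query_ball_point(grid, burial_radius,
                                         return_length=True)
    for i, p in enumerate(grid):
        if counts[i] < burial_min:
            continue
        neigh = occ_tree.query_ball_point(p, max_reach)
        if neigh:
            d = np.linalg.norm(occ_coords[neigh] - p, axis=1)
            if np.any(d < occ_radii[neigh] + probe_radius):
                continue
        keep[i] = True
    return grid[keep]


def grow_pocket(spheres: np.ndarray,
                ligand_atoms: Sequence[AtomRecord],
                linkage: float = DEFAULT_LINKAGE) -> PocketModel:
    """Grow the pocket sphere set outward from the ligand centre.

    Spheres are sorted by ascending distance to the ligand's geometric
    centre (ties broken lexicographically by coordinates); the nearest is
    accepted, then the sorted list is re-scanned until a full pass accepts
    nothing, accepting any sphere strictly within ``linkage`` of an
    accepted one.  Returns a partial PocketModel (no surface atoms yet).
    """
    spheres = np.asarray(spheres, dtype=float)
    if spheres.size == 0:
        raise PocketDetectionError("no candidate spheres to grow from")
    if not ligand_atoms:
        raise PocketDetectionError("no ligand atoms for pocket growth")

    center = np.vstack([a.pos for a in ligand_atoms]).mean(axis=0)
    dist = np.linalg.norm(spheres - center, axis=1)
    order = np.lexsort((spheres[:, 2], spheres[:, 1], spheres[:, 0], dist))
    pts = spheres[order]

    accepted = np.zeros(len(pts), dtype=bool)
    accepted[0] = True
    tree = cKDTree(pts)
    changed = True
    while changed:
        changed = False
        acc_tree = cKDTree(pts[accepted])
        d, _ = acc_tree.query(pts)
        newly = (~accepted) & (d < linkage)
        if np.any(newly):
            accepted |= newly
            changed = True

    centers = pts[accepted]
    lig_box = bounding_box(np.vstack([a.pos for a in ligand_atoms]))
    return PocketModel(sphere_centers=centers,
                       pocket_box=bounding_box(centers),
                       ligand_box=lig_box)


def extract_relevant_atoms(structure: Structure,
                           surface: SurfaceAtomSet,
                           pocket_box: tuple[np.ndarray, np.ndarray],
                           ligand_box: tuple[np.ndarray, np.ndarray],
                           margin: float = DEFAULT_BOX_MARGIN
                           ) -> list[AtomRecord]:
    """SES-contributing atoms strictly within ``margin`` of either box."""
    members = sorted(surface.atom_indices)
    if not members:
        raise EmptyPocketSurfaceError(f"{structure.id}: empty surface set")
    coords = np.vstack([structure.atoms[i].pos for i in members])
    d = np.minimum(box_distance(coords, pocket_box),
                   box_distance(coords, ligand_box))
    kept = [structure.atoms[members[i]] for i in np.nonzero(d < margin)[0]]
    if not kept:
        raise EmptyPocketSurfaceError(
            f"{structure.id}: no surface atom within {margin} Å of the pocket")
    return kept


def detect_pocket(structure: Structure,
                  surface: Optional[SurfaceAtomSet] = None,
                  burial_min: int = DEFAULT_BURIAL_MIN,
                  burial_radius: float = DEFAULT_BURIAL_RADIUS,
                  lattice: float = DEFAULT_LATTICE,
                  linkage: float = DEFAULT_LINKAGE,
                  margin: float = DEFAULT_BOX_MARGIN) -> PocketModel:
    """Full pipeline: SES set → buried spheres → growth → relevant atoms."""
    if surface is None:
        surface = ses_contributing_atoms(structure)
    spheres = place_buried_spheres(structure, surface,
                                   burial_min=burial_min,
                                   burial_radius=burial_radius,
                                   lattice=lattice)
    if spheres.size == 0:
        raise PocketDetectionError(
            f"{structure.id}: no buried sphere candidates survive")
    pocket = grow_pocket(spheres, structure.ligand_atoms, linkage=linkage)
    pocket.surface_atoms = extract_relevant_atoms(
        structure, surface, pocket.pocket_box, pocket.ligand_box, margin)
    pocket.structure = structure
    return pocket
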