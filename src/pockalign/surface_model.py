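"""Solvent-excluded-surface (SES) membership of protein atoms.

The downstream pocket pipeline needs only to know *which* atoms touch the
solvent-excluded surface, not the surface mesh itself.  An atom is taken to
contribute to the SES if a solvent probe (radius 1.4 Å) can be placed
tangent to it without overlapping any other atom — tested over a
quasi-uniform sample of directions — or, failing that, if a probe resting
on two such accessible neighbours still touches the atom (a re-entrant
contact).  Retained crystallographic waters count as surface-forming atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyProteinError
from .structure_io import Structure

logger = logging.getLogger(__name__)

#: van der Waals radii (Å), Bondi-style published values.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "B": 1.92,
}
FALLBACK_RADIUS = 1.70

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_DIRECTIONS = 256


def vdw_radius(element: str) -> float:
    """vdW radius for an element symbol; unknown elements fall back to 1.70 Å."""
    el = element.upper()
    if el not in VDW_RADII:
        logger.warning("no vdW radius for element %r; using fallback %.2f Å",
                       element, FALLBACK_RADIUS)
        return FALLBACK_RADIUS
    return VDW_RADII[el]


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice on the sphere)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SurfaceAtomSet:
    """Indices (into Structure.atoms) of SES-contributing atoms."""

    atom_indices: set[int]
    probe_radius: float = DEFAULT_PROBE_RADIUS
    radii_table: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __contains__(self, idx: int) -> bool:
        return idx in self.atom_indices


def _probe_accessible(coords: np.ndarray, radii: np.ndarray, tree: cKDTree,
                      i: int, directions: np.ndarray, probe: float,
                      eps: float = 1e-9) -> bool:
    """Can a probe be placed tangent to atom i in one of the directions?"""
    centers = coords[i] + (radii[i] + probe) * directions
    reach = radii.max() + probe
    neigh = tree.query_ball_point(coords[i], 2.0 * probe + radii[i] + reach)
    neigh = [j for j in neigh if j != i]
    if not neigh:
        return True
    d = np.linalg.norm(centers[:, None, :] - coords[neigh][None, :, :], axis=2)
    clear = radii[neigh][None, :] + probe - eps
    return bool(np.any(np.all(d >= clear, axis=1)))


def _reentrant_contact(coords: np.ndarray, radii: np.ndarray, tree: cKDTree,
                       i: int, accessible: np.ndarray, probe: float,
                       n_circle: int = 32, eps: float = 1e-9) -> bool:
    """Does a probe tangent to atom i and to an accessible neighbour fit?

    Samples the circle of probe centres simultaneously tangent to atoms i
    and j for every accessible neighbour j; if any sampled position is free
    of overlap with all other atoms, atom i touches a re-entrant patch.
    """
    reach = radii.max() + probe
    neigh = tree.query_ball_point(coords[i], radii[i] + 2.0 * probe + reach)
    t = np.linspace(0.0, 2.0 * np.pi, n_circle, endpoint=False)
    for j in neigh:
        if j == i or not accessible[j]:
            continue
        ri, rj = radii[i] + probe, radii[j] + probe
        axis = coords[j] - coords[i]
        d = np.linalg.norm(axis)
        if d < eps or d >= ri + rj:
            continue
        # circle of points at distance ri from i and rj from j
        a = (d * d + ri * ri - rj * rj) / (2.0 * d)
        h2 = ri * ri - a * a
        if h2 <= 0.0:
            continue
        h = np.sqrt(h2)
        u = axis / d
        ref = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        v = np.cross(u, ref)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        centers = (coords[i] + a * u
                   + h * (np.cos(t)[:, None] * v + np.sin(t)[:, None] * w))
        others = [k for k in tree.query_ball_point(coords[i], a + h + reach)
                  if k not in (i, j)]
        if not others:
            return True
        dist = np.linalg.norm(centers[:, None, :] - coords[others][None, :, :],
                              axis=2)
        clear = radii[others][None, :] + probe - eps
        if np.any(np.all(dist >= clear, axis=1)):
            return True
    return False


def ses_contributing_atoms(structure: Structure,
                           probe_radius: float = DEFAULT_PROBE_RADIUS,
                           n_directions: int = DEFAULT_N_DIRECTIONS,
                           include_reentrant: bool = True) -> SurfaceAtomSet:
    """Indices of protein (and retained water) atoms touching the SES.

    Raises EmptyProteinError if the structure has no protein atoms.
    """
    idx = [i for i, a in enumerate(structure.atoms)
           if a.record_class in ("protein", "water")]
    if not any(structure.atoms[i].record_class == "protein" for i in idx):
        raise EmptyProteinError(f"{structure.id}: no protein atoms")

    coords = np.vstack([structure.atoms[i].pos for i in idx])
    radii = np.array([vdw_radius(structure.atoms[i].element) for i in idx])
    tree = cKDTree(coords)
    directions = fibonacci_sphere(n_directions)

    accessible = np.zeros(len(idx), dtype=bool)
    for k in range(len(idx)):
        accessible[k] = _probe_accessible(coords, radii, tree, k,
                                          directions, probe_radius)
    contributing = accessible.copy()
    if include_reentrant:
        for k in np.nonzero(~accessible)[0]:
            if _reentrant_contact(coords, radii, tree, k, accessible,
                                  probe_radius):
                contributing[k] = True

    members = {idx[k] for k in np.nonzero(contributing)[0]}
    return SurfaceAtomSet(atom_indices=members, probe_radius=probe_radius)
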