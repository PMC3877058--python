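"""Rigid superposition of two pocket grids by FFT correlation.

The template pocket is rotated over a coarse Euler lattice (20° steps about
the global X, Y and Z axes, applied as R = Rz(γ)·Ry(β)·Rx(α), about the
centroid of its pocket spheres), re-gridded after each rotation, and the
correlation of the query grid f with every cyclic translation of the
template grid g is obtained at once as IFT(conj(DFT(f))·DFT(g)) — the
Katchalski-Katzir trick, here applied to pocket overlays rather than
docking poses.  Both grids are zero-padded to a common box of at least
dim_f + dim_g per axis so the reported argmax is free of wrap-around
aliasing.  The global argmax over rotations and shifts, with ties broken
by the first candidate in lexicographic (α, β, γ, x₀, y₀, z₀) order, is
returned together with the equivalent real-space rigid transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import scipy.fft

from .errors import GridError
from .grid_builder import (DEFAULT_PAD, DEFAULT_RESOLUTION, OccupancyGrid,
                           build_grid, default_value_map, grid_from_points)
from .pocket_model import PocketModel

logger = logging.getLogger(__name__)

DEFAULT_ANGLE_STEP = 20.0  # degrees
_BATCH = 243               # rotations per batched FFT block


@dataclass(frozen=True)
class RotationSample:
    """Euler angles (degrees) on the search lattice, order R = Rz·Ry·Rx."""

    alpha: float
    beta: float
    gamma: float

    def matrix(self) -> np.ndarray:
        return euler_matrix(self.alpha, self.beta, self.gamma)


def euler_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix R = Rz(γ)·Ry(β)·Rx(α), angles in degrees."""
    a, b, g = np.deg2rad([alpha, beta, gamma])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotation_lattice(angle_step: float = DEFAULT_ANGLE_STEP
                     ) -> list[RotationSample]:
    """All (360/step)³ Euler samples, lexicographic in (α, β, γ)."""
    angles = np.arange(0.0, 360.0, angle_step)
    return [RotationSample(a, b, g)
            for a in angles for b in angles for g in angles]


@dataclass
class RigidTransform:
    """Real-space rigid map p ↦ R·p + t (Å)."""

    rotation: np.ndarray   # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    """Optimal rotation/translation of the template grid onto the query."""

    rotation: RotationSample
    shift: tuple[int, int, int]     # grid cells, sign-unwrapped
    correlation: float
    transform: RigidTransform       # template coords → query frame (Å)


def rotate_template(pocket: PocketModel, r: RotationSample) -> PocketModel:
    """Rotate template surface atoms and spheres about the sphere centroid.

    Returns a new PocketModel with rotated coordinates; grids are rebuilt
    from the rotated points afterwards (no grid resampling).
    """
    rot = r.matrix()
    center = pocket.sphere_centroid
    def _map(p: np.ndarray) -> np.ndarray:
        return (p - center) @ rot.T + center

    atoms = [dc_replace(a, pos=_map(a.pos)) for a in pocket.surface_atoms]
    sph = np.asarray(pocket.sphere_centers, float).reshape(-1, 3)
    sph_rot = _map(sph) if sph.size else sph
    boxes = []
    for box in (pocket.pocket_box, pocket.ligand_box):
        corners = _map(np.array(np.meshgrid(*zip(*box), indexing="ij"))
                       .reshape(3, -1).T)
        boxes.append((corners.min(axis=0), corners.max(axis=0)))
    return PocketModel(sphere_centers=sph_rot, pocket_box=boxes[0],
                       ligand_box=boxes[1], surface_atoms=atoms,
                       structure=pocket.structure)


def _as_array(grid) -> np.ndarray:
    return grid.values if isinstance(grid, OccupancyGrid) else np.asarray(grid, float)


def pad_to_common(f, g, shape: tuple[int, int, int] | None = None
                  ) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Embed both arrays at index 0 of a common box ≥ dim_f + dim_g."""
    fa, ga = _as_array(f), _as_array(g)
    if shape is None:
        shape = tuple(scipy.fft.next_fast_len(a + b, real=True)
                      for a, b in zip(fa.shape, ga.shape))
    if any(s < a + b for s, a, b in zip(shape, fa.shape, ga.shape)):
        raise GridError("common box smaller than dim_f + dim_g")
    fp = np.zeros(shape)
    gp = np.zeros(shape)
    fp[tuple(slice(0, n) for n in fa.shape)] = fa
    gp[tuple(slice(0, n) for n in ga.shape)] = ga
    return fp, gp, shape


def cyclic_correlation_fft(fa: np.ndarray, ga: np.ndarray) -> np.ndarray:
    """c(t) = Σ_x f(x)·g(x+t) for all cyclic shifts t, via real FFTs."""
    if fa.shape != ga.shape:
        raise GridError(f"shape mismatch {fa.shape} vs {ga.shape}")
    fh = scipy.fft.rfftn(fa)
    gh = scipy.fft.rfftn(ga)
    return scipy.fft.irfftn(np.conj(fh) * gh, s=fa.shape)


def correlate_fft(f, g) -> np.ndarray:
    """Correlation of two grids over every cyclic shift of the common box."""
    fp, gp, _ = pad_to_common(f, g)
    return cyclic_correlation_fft(fp, gp)


def brute_force_correlation(f, g, shift: tuple[int, int, int]) -> float:
    """Direct Σ f(l,m,n)·g(l+x₀, m+y₀, n+z₀) with cyclic indexing.

    Test oracle for the FFT path; intended for small grids (≤ ~16³).
    """
    fp, gp, _ = pad_to_common(f, g)
    rolled = np.roll(gp, shift=[-int(s) for s in shift], axis=(0, 1, 2))
    return float(np.sum(fp * rolled))


def _unwrap_shift(t: np.ndarray, dims_g: np.ndarray, shape: np.ndarray
                  ) -> np.ndarray:
    """Map cyclic shifts to signed shifts: t ≥ dim_g means negative."""
    t = np.asarray(t, int).copy()
    neg = t >= dims_g
    t[neg] -= shape[neg]
    return t


def find_best_superposition(query: PocketModel,
                            template: PocketModel,
                            angle_step: float = DEFAULT_ANGLE_STEP,
                            resolution: float = DEFAULT_RESOLUTION,
                            pad: int = DEFAULT_PAD,
                            value_map: dict[str, float] | None = None,
                            ) -> SuperpositionResult:
    """Exhaustive search over the rotation lattice for the best overlay.

    For each rotation the template points are rotated about their sphere
    centroid, re-gridded, and correlated with the fixed query grid via FFT;
    the global maximum over all rotations and cyclic shifts is returned.
    Ties are resolved by the first candidate in (α, β, γ, x₀, y₀, z₀)
    lexicographic order (strict > comparison, no epsilon).
    """
    if query.n_surf == 0 or template.n_surf == 0:
        raise GridError("both pockets need at least one surface atom")
    if value_map is None:
        value_map = default_value_map()

    f_grid = build_grid(query, resolution=resolution, pad=pad,
                        value_map=value_map)
    f_dims = np.array(f_grid.shape)

    # Rotation-independent bound on the template grid size: every rotated
    # point stays within the bounding sphere about the rotation centre.
    center = template.sphere_centroid
    pts = template.surface_coords
    sph = np.asarray(template.sphere_centers, float).reshape(-1, 3)
    allpts = pts if sph.size == 0 else np.vstack([pts, sph])
    radius = float(np.max(np.linalg.norm(allpts - center, axis=1)))
    g_dims_max = int(np.ceil(2.0 * (radius + pad * resolution) / resolution)) + 2
    shape = tuple(scipy.fft.next_fast_len(int(fd) + g_dims_max, real=True)
                  for fd in f_dims)

    fp = np.zeros(shape)
    fp[tuple(slice(0, n) for n in f_dims)] = f_grid.values
    # the batched scan runs in single precision for speed; the winning
    # correlation is recomputed below in double precision by direct sum
    fh_conj = np.conj(scipy.fft.rfftn(fp.astype(np.float32)))

    t_surf = template.surface_coords
    lattice = rotation_lattice(angle_step)
    best = None  # (corr, rotation, shift_cyclic, g_values, g_origin, g_dims)
    for start in range(0, len(lattice), _BATCH):
        chunk = lattice[start:start + _BATCH]
        stack = np.zeros((len(chunk),) + shape, dtype=np.float32)
        metas = []
        for bi, rot in enumerate(chunk):
            rmat = rot.matrix()
            g_grid = grid_from_points(
                (t_surf - center) @ rmat.T + center,
                (sph - center) @ rmat.T + center if sph.size else sph,
                resolution=resolution, pad=pad, value_map=value_map)
            gd = g_grid.shape
            if any(s < f + g for s, f, g in zip(shape, f_dims, gd)):
                raise GridError("rotated template exceeds the common box")
            stack[(bi,) + tuple(slice(0, n) for n in gd)] = g_grid.values
            metas.append((g_grid.values, g_grid.origin, np.array(gd)))
        gh = scipy.fft.rfftn(stack, axes=(1, 2, 3))
        corr = scipy.fft.irfftn(fh_conj[None] * gh, s=shape, axes=(1, 2, 3))
        for bi, rot in enumerate(chunk):
            flat = int(np.argmax(corr[bi]))
            c = float(corr[bi].reshape(-1)[flat])
            if best is None or c > best[0]:
                t = np.array(np.unravel_index(flat, shape))
                best = (c, rot, t) + metas[bi]

    _, rot, t_cyc, g_values, g_origin, g_dims = best
    t_signed = _unwrap_shift(t_cyc, g_dims, np.array(shape))
    gp = np.zeros(shape)
    gp[tuple(slice(0, n) for n in g_values.shape)] = g_values
    c = float(np.sum(fp * np.roll(gp, shift=-t_cyc, axis=(0, 1, 2))))

    # template point q (original frame): rotate about centre, then the grid
    # alignment moves it by (origin_f - origin_g) - t·resolution.
    rmat = rot.matrix()
    delta = f_grid.origin - g_origin - t_signed * resolution
    translation = center - rmat @ center + delta
    transform = RigidTransform(rotation=rmat, translation=translation)
    return SuperpositionResult(rotation=rot,
                               shift=tuple(int(x) for x in t_signed),
                               correlation=c,
                               transform=transform)
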