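"""Signed occupancy grids for pocket-surface correlation.

Each 1 Å grid cell is classified from its centre point: *surface* when
strictly within 1.8 Å of any extracted pocket-surface atom, otherwise
*pocket* when strictly within 1.8 Å of any pocket sphere centre, otherwise
*above_surface* when within the 1 Å shell just beyond the surface band
(strictly within 2.8 Å of a surface atom), otherwise *elsewhere*.  The
category values are chosen so that the product-sum correlation rewards
surface-on-surface and pocket-on-pocket overlap and penalises placing
surface on pocket: {surface: +1, above_surface: +0.5, pocket: −1,
elsewhere: 0}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GridError
from .pocket_model import PocketModel

SURFACE_THRESHOLD = 1.8       # Å, strict <
ABOVE_SURFACE_THRESHOLD = 2.8  # Å, strict < (1 Å shell beyond the surface band)
POCKET_THRESHOLD = 1.8        # Å, strict <
DEFAULT_RESOLUTION = 1.0      # Å per cell
DEFAULT_PAD = 2               # cells on each side

CATEGORIES = ("surface", "above_surface", "pocket", "elsewhere")


def default_value_map() -> dict[str, float]:
    """Signed cell values: surface·surface > 0, pocket·pocket > 0,
    surface·pocket < 0."""
    return {"surface": 1.0, "above_surface": 0.5,
            "pocket": -1.0, "elsewhere": 0.0}


@dataclass
class OccupancyGrid:
    """A signed 3-D scalar lattice with real-space placement."""

    values: np.ndarray                 # (nx, ny, nz) float
    origin: np.ndarray                 # Å, min corner of cell (0,0,0)
    resolution: float = DEFAULT_RESOLUTION
    value_map: dict[str, float] = field(default_factory=default_value_map)
    categories: Optional[np.ndarray] = None  # same shape, int codes

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def cell_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of cell-centre coordinates (Å)."""
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in self.shape],
                                   indexing="ij"), axis=-1)
        return self.origin + (idx + 0.5) * self.resolution


def _stamp(mask: np.ndarray, points: np.ndarray, origin: np.ndarray,
           resolution: float, radius: float) -> None:
    """Mark cells whose centre is strictly within ``radius`` of any point."""
    if points.size == 0:
        return
    dims = np.array(mask.shape)
    half = int(np.ceil(radius / resolution)) + 1
    off = np.arange(-half, half + 1)
    window = np.stack(np.meshgrid(off, off, off, indexing="ij"),
                      axis=-1).reshape(-1, 3)
    base = np.floor((points - origin) / resolution - 0.5).astype(int)
    cand = base[:, None, :] + window[None, :, :]           # (P, W, 3)
    centers = origin + (cand + 0.5) * resolution
    d2 = np.sum((centers - points[:, None, :]) ** 2, axis=-1)
    sel = cand[d2 < radius * radius]
    ok = np.all((sel >= 0) & (sel < dims), axis=1)
    sel = sel[ok]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True


def build_grid(pocket: PocketModel,
               resolution: float = DEFAULT_RESOLUTION,
               pad: int = DEFAULT_PAD,
               value_map: Optional[dict[str, float]] = None,
               box: Optional[tuple[np.ndarray, int | tuple[int, int, int]]] = None,
               ) -> OccupancyGrid:
    """Voxelize a pocket model into a signed occupancy grid.

    The grid covers all surface atoms and sphere centres plus ``pad`` cells
    on each side; ``box=(origin, dims)`` overrides that placement (used to
    compare grids in a fixed frame).  Category precedence is
    surface > pocket > above_surface > elsewhere.
    """
    surf = pocket.surface_coords
    sph = np.asarray(pocket.sphere_centers, dtype=float).reshape(-1, 3)
    return grid_from_points(surf, sph, resolution=resolution, pad=pad,
                            value_map=value_map, box=box)


def grid_from_points(surf: np.ndarray, sph: np.ndarray,
                     resolution: float = DEFAULT_RESOLUTION,
                     pad: int = DEFAULT_PAD,
                     value_map: Optional[dict[str, float]] = None,
                     box=None) -> OccupancyGrid:
    """build_grid on raw coordinate arrays (hot path of the rotation scan)."""
    if value_map is None:
        value_map = default_value_map()
    surf = np.asarray(surf, float).reshape(-1, 3)
    sph = np.asarray(sph, float).reshape(-1, 3)
    if surf.size == 0:
        raise GridError("pocket has no surface atoms to grid")

    pts = surf if sph.size == 0 else np.vstack([surf, sph])
    if box is None:
        lo = pts.min(axis=0) - pad * resolution
        hi = pts.max(axis=0) + pad * resolution
        dims = np.ceil((hi - lo) / resolution).astype(int) + 1
        origin = lo
    else:
        origin, d = box
        origin = np.asarray(origin, dtype=float)
        dims = np.full(3, d, dtype=int) if np.isscalar(d) else np.asarray(d, int)

    shape = tuple(int(n) for n in dims)
    surf_mask = np.zeros(shape, dtype=bool)
    near_mask = np.zeros(shape, dtype=bool)
    pocket_mask = np.zeros(shape, dtype=bool)
    _stamp(surf_mask, surf, origin, resolution, SURFACE_THRESHOLD)
    _stamp(near_mask, surf, origin, resolution, ABOVE_SURFACE_THRESHOLD)
    _stamp(pocket_mask, sph, origin, resolution, POCKET_THRESHOLD)

    codes = np.full(shape, CATEGORIES.index("elsewhere"), dtype=np.int8)
    codes[near_mask] = CATEGORIES.index("above_surface")
    codes[pocket_mask & ~surf_mask] = CATEGORIES.index("pocket")
    codes[surf_mask] = CATEGORIES.index("surface")

    values = np.zeros(shape, dtype=float)
    for ci, cat in enumerate(CATEGORIES):
        values[codes == ci] = value_map[cat]
    return OccupancyGrid(values=values, origin=np.asarray(origin, float),
                         resolution=resolution, value_map=dict(value_map),
                         categories=codes)


def classify_point(pocket: PocketModel, point: np.ndarray) -> str:
    """Brute-force category of a single location (test oracle)."""
    p = np.asarray(point, dtype=float)
    surf = pocket.surface_coords
    sph = np.asarray(pocket.sphere_centers, float).reshape(-1, 3)
    d_surf = np.min(np.linalg.norm(surf - p, axis=1)) if surf.size else np.inf
    d_sph = np.min(np.linalg.norm(sph - p, axis=1)) if sph.size else np.inf
    if d_surf < SURFACE_THRESHOLD:
        return "surface"
    if d_sph < POCKET_THRESHOLD:
        return "pocket"
    if d_surf < ABOVE_SURFACE_THRESHOLD:
        return "above_surface"
    return "elsewhere"


def export_grid_text(grid: OccupancyGrid, path) -> None:
    """Dump a grid as a simple text voxel format (debugging aid)."""
    with open(path, "w") as fh:
        fh.write(f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} "
                 f"{grid.origin[2]:.6f}\n")
        fh.write(f"resolution {grid.resolution:.6f}\n")
        fh.write(f"dims {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n")
        np.savetxt(fh, grid.values.reshape(-1), fmt="%.3f")
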