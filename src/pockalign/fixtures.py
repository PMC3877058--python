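"""Synthetic co-crystal fixtures with known pockets and known transforms.

`make_cavity_protein` builds a globular all-carbon atom cloud (a jittered
cubic close packing inside a ball) with a spherical cavity carved out at
the surface — a surface-breaching binding pocket — and a small "ligand"
atom cluster placed inside the cavity.  `make_transformed_copy` produces a
rigidly moved copy with the applied transform recorded, giving ground
truth for superposition-recovery tests.  All randomness is fixed by the
seed; fixtures are deliberately not physically realistic proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import numpy as np

from .errors import FixtureSpecError
from .structure_io import AtomRecord, Structure
from .superposer import RigidTransform, RotationSample

DEFAULT_SHELL_RADIUS = 12.0
DEFAULT_CAVITY_RADIUS = 4.0
DEFAULT_ATOM_SPACING = 3.0
DEFAULT_LIGAND_ATOMS = 3


@dataclass
class FixtureSpec:
    """Geometry of a synthetic cavity 'protein'."""

    shell_radius: float = DEFAULT_SHELL_RADIUS
    cavity_radius: float = DEFAULT_CAVITY_RADIUS
    cavity_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    atom_spacing: float = DEFAULT_ATOM_SPACING
    ligand_atom_count: int = DEFAULT_LIGAND_ATOMS
    seed: int = 0

    def __post_init__(self) -> None:
        self.cavity_direction = np.asarray(self.cavity_direction, float)
        norm = np.linalg.norm(self.cavity_direction)
        if norm == 0:
            raise FixtureSpecError("cavity_direction must be non-zero")
        self.cavity_direction = self.cavity_direction / norm
        if not self.cavity_radius < self.shell_radius:
            raise FixtureSpecError("cavity_radius must be < shell_radius")
        if not 2.5 <= self.atom_spacing <= 4.0:
            raise FixtureSpecError("atom_spacing must lie in [2.5, 4.0] Å")
        if self.ligand_atom_count < 1:
            raise FixtureSpecError("need at least one ligand atom")

    @property
    def cavity_center(self) -> np.ndarray:
        return (self.shell_radius - self.cavity_radius) * self.cavity_direction


def make_cavity_protein(spec: FixtureSpec,
                        structure_id: str = "fixture") -> Structure:
    """Deterministic all-carbon ball with a carved surface cavity + ligand."""
    rng = np.random.default_rng(spec.seed)
    s = spec.atom_spacing
    n = int(np.ceil(spec.shell_radius / s)) + 1
    ax = np.arange(-n, n + 1) * s
    lattice = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"),
                       axis=-1).reshape(-1, 3)
    jitter = rng.uniform(-0.15 * s, 0.15 * s, size=lattice.shape)
    pts = lattice + jitter
    c = spec.cavity_center
    inside_ball = np.linalg.norm(pts, axis=1) <= spec.shell_radius
    outside_cavity = np.linalg.norm(pts - c, axis=1) > spec.cavity_radius
    protein_pts = pts[inside_ball & outside_cavity]
    if len(protein_pts) == 0:
        raise FixtureSpecError("no protein atoms survive the carve")

    # one single-Cα residue per atom, with a seeded random amino-acid type
    # so unrelated fixtures have realistically low sequence identity
    aa3 = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
           "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
           "TYR", "VAL"]
    res_types = rng.integers(0, len(aa3), size=len(protein_pts))
    atoms: list[AtomRecord] = []
    serial = 0
    for i, p in enumerate(protein_pts):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name="CA", element="C", pos=p,
            residue_name=aa3[res_types[i]], residue_seq=i + 1, chain="A",
            record_class="protein"))

    # compact ligand cluster just inside the cavity (biased slightly inward
    # so the cavity mouth stays open)
    lig_center = c - 0.5 * spec.cavity_direction
    offsets = 1.4 * _unit_cluster(spec.ligand_atom_count)
    for k, off in enumerate(offsets):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=f"C{k + 1}", element="C",
            pos=lig_center + off, residue_name="LIG", residue_seq=1,
            chain="L", record_class="ligand"))
    return Structure(id=structure_id, atoms=atoms)


def _unit_cluster(n: int) -> np.ndarray:
    """n points of a fixed compact cluster around the origin."""
    base = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
        [0.0, 0.0, 1.0], [-1.0, 0.0, 0.0], [0.0, -1.0, 0.0],
        [0.0, 0.0, -1.0], [0.7, 0.7, 0.0], [0.0, 0.7, 0.7],
        [0.7, 0.0, 0.7],
    ])
    if n > len(base):
        raise FixtureSpecError(f"at most {len(base)} ligand atoms supported")
    return base[:n]


_BB_GEOMETRY = {
    # bond lengths (Å) and angles (deg) of an idealized peptide backbone
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8, "omega": 180.0,
}


def _extend(a: np.ndarray, b: np.ndarray, c: np.ndarray,
            bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors, internal coordinates (NeRF)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(torsion),
                        bond * np.sin(angle) * np.sin(torsion)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_backbone(n_residues: int, phi: float, psi: float,
                        structure_id: str = "peptide",
                        chain: str = "A") -> Structure:
    """Poly-alanine backbone (N, CA, C, O) at fixed (φ, ψ), ω = 180°.

    φ = −57°, ψ = −47° gives an ideal α-helix; φ = −180°, ψ = 180° a fully
    extended chain.  Used to exercise the secondary-structure assigner.
    """
    g = _BB_GEOMETRY
    if n_residues < 1:
        raise FixtureSpecError("need at least one residue")
    # seed triad for residue 1
    coords: dict[tuple[int, str], np.ndarray] = {}
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([g["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(g["ang_n_ca_c"])
    coords[(0, "C")] = coords[(0, "CA")] + g["ca_c"] * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_residues):
        if i > 0:
            coords[(i, "N")] = _extend(coords[(i - 1, "N")],
                                       coords[(i - 1, "CA")],
                                       coords[(i - 1, "C")],
                                       g["c_n"], g["ang_ca_c_n"], psi)
            coords[(i, "CA")] = _extend(coords[(i - 1, "CA")],
                                        coords[(i - 1, "C")],
                                        coords[(i, "N")],
                                        g["n_ca"], g["ang_c_n_ca"],
                                        g["omega"])
            coords[(i, "C")] = _extend(coords[(i - 1, "C")],
                                       coords[(i, "N")],
                                       coords[(i, "CA")],
                                       g["ca_c"], g["ang_n_ca_c"], phi)
        if i < n_residues - 1:
            # O needs psi; place after next N exists using the torsion rule
            pass
    for i in range(n_residues):
        coords[(i, "O")] = _extend(coords[(i, "N")], coords[(i, "CA")],
                                   coords[(i, "C")],
                                   g["c_o"], g["ang_ca_c_o"], psi - 180.0)

    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(n_residues):
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=name, element=name[0], pos=coords[(i, name)],
                residue_name="ALA", residue_seq=i + 1, chain=chain,
                record_class="protein"))
    return Structure(id=structure_id, atoms=atoms)


def make_transformed_copy(structure: Structure,
                          rotation: RotationSample,
                          translation: np.ndarray,
                          about: Optional[np.ndarray] = None,
                          invert_rotation: bool = False,
                          ) -> tuple[Structure, RigidTransform]:
    """Rigidly transformed copy plus the applied transform.

    Rotation is about ``about`` (default: the ligand centroid), then the
    translation is added.  With ``invert_rotation`` the inverse of the
    lattice rotation is applied, so a lattice search can recover it exactly.
    """
    rmat = rotation.matrix()
    if invert_rotation:
        rmat = rmat.T
    translation = np.asarray(translation, float)
    if about is None:
        lig = structure.ligand_atoms
        pts = (np.vstack([a.pos for a in lig]) if lig
               else structure.coords())
        about = pts.mean(axis=0)
    about = np.asarray(about, float)
    transform = RigidTransform(rotation=rmat,
                               translation=about - rmat @ about + translation)
    atoms = [dc_replace(a, pos=transform.apply(a.pos))
             for a in structure.atoms]
    return Structure(id=structure.id + "_moved", atoms=atoms), transform
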