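"""Reading protein–ligand co-crystal structures.

Parses PDB files (via gemmi), classifies every atom as protein, ligand,
water or other heteroatom, selects the reference ligand, and applies the
water-retention rule.  Only MODEL 1 is used and only the first alternate
location per atom name is kept, so downstream geometry sees a single
deterministic conformer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, MissingLigandError, UnknownElementError

logger = logging.getLogger(__name__)

RecordClass = Literal["protein", "ligand", "water", "other-het"]

#: IUPAC standard atomic weights (g/mol) for elements common in PDB entries.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974,
    "S": 32.06, "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938,
    "FE": 55.845, "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38,
    "SE": 78.971, "BR": 79.904, "I": 126.904,
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, in the classification used downstream."""

    serial: int
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Å
    residue_name: str
    residue_seq: int
    chain: str
    record_class: RecordClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class Structure:
    """A parsed co-crystal structure with per-atom record classes."""

    id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def atoms_of(self, record_class: RecordClass) -> list[AtomRecord]:
        return [a for a in self.atoms if a.record_class == record_class]

    @property
    def protein_atoms(self) -> list[AtomRecord]:
        return self.atoms_of("protein")

    @property
    def ligand_atoms(self) -> list[AtomRecord]:
        return self.atoms_of("ligand")

    @property
    def water_atoms(self) -> list[AtomRecord]:
        return self.atoms_of("water")

    def coords(self, atoms: Optional[Sequence[AtomRecord]] = None) -> np.ndarray:
        """(n, 3) coordinate array for ``atoms`` (default: all atoms)."""
        sel = self.atoms if atoms is None else atoms
        if not sel:
            return np.zeros((0, 3))
        return np.vstack([a.pos for a in sel])

    @property
    def sequence_by_chain(self) -> dict[str, str]:
        """One-letter sequences derived from protein records, per chain."""
        seqs: dict[str, list[str]] = {}
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.record_class != "protein":
                continue
            key = (a.chain, a.residue_seq)
            if key in seen:
                continue
            seen.add(key)
            seqs.setdefault(a.chain, []).append(_one_letter(a.residue_name))
        return {c: "".join(s) for c, s in seqs.items()}

    @property
    def sequence(self) -> str:
        """All protein chains concatenated in chain-ID order."""
        by_chain = self.sequence_by_chain
        return "".join(by_chain[c] for c in sorted(by_chain))


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha():
            return code
    return "X"


def _classify_residue(residue: gemmi.Residue) -> RecordClass:
    name = residue.name.upper()
    if name in WATER_NAMES:
        return "water"
    info = gemmi.find_tabulated_residue(residue.name)
    if residue.het_flag == "A" and info is not None and info.is_amino_acid():
        return "protein"
    return "other-het"


def read_structure(path: str | Path,
                   ligand_selector: Optional[str] = None) -> Structure:
    """Read a PDB file and select the reference ligand.

    Parameters
    ----------
    path:
        PDB file with ATOM/HETATM records.
    ligand_selector:
        ``"NAME"``, ``"NAME:CHAIN"`` or ``"NAME:CHAIN:RESSEQ"`` naming the
        HETATM group to use as reference ligand.  Without a selector the
        largest-by-atom-count non-water HETATM group is chosen (ties broken
        by chain then residue number).

    Raises
    ------
    FormatError
        if the file cannot be parsed or contains no atoms.
    MissingLigandError
        if no non-water HETATM group exists or the selector matches nothing.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no coordinate model in {path}")

    model = st[0]  # MODEL 1 only
    atoms: list[AtomRecord] = []
    serial = 0
    for chain in model:
        for residue in chain:
            cls = _classify_residue(residue)
            seen_names: set[str] = set()
            for atom in residue:
                if atom.name in seen_names:
                    continue  # keep first altloc per atom name
                seen_names.add(atom.name)
                serial += 1
                atoms.append(AtomRecord(
                    serial=serial,
                    name=atom.name,
                    element=atom.element.name.upper(),
                    pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    residue_name=residue.name,
                    residue_seq=residue.seqid.num,
                    chain=chain.name,
                    record_class=cls,
                ))
    if not atoms:
        raise FormatError(f"no ATOM/HETATM records in {path}")

    structure = Structure(id=path.stem, atoms=atoms)
    return select_ligand(structure, ligand_selector)


def select_ligand(structure: Structure,
                  ligand_selector: Optional[str] = None) -> Structure:
    """Mark one HETATM group as the reference ligand (record_class 'ligand')."""
    groups: dict[tuple[str, str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.record_class in ("other-het", "ligand"):
            groups.setdefault((a.chain, a.residue_name, a.residue_seq), []).append(i)
    if not groups:
        raise MissingLigandError(
            f"{structure.id}: no non-water HETATM group present")

    if ligand_selector is not None:
        parts = ligand_selector.split(":")
        name = parts[0]
        chain = parts[1] if len(parts) > 1 and parts[1] else None
        seq = int(parts[2]) if len(parts) > 2 and parts[2] else None
        candidates = [k for k in groups
                      if k[1] == name
                      and (chain is None or k[0] == chain)
                      and (seq is None or k[2] == seq)]
        if not candidates:
            raise MissingLigandError(
                f"{structure.id}: no HETATM group matches {ligand_selector!r}")
    else:
        candidates = list(groups)

    # largest group wins; deterministic tie-break by (chain, resseq, name)
    chosen = max(sorted(candidates), key=lambda k: len(groups[k]))
    chosen_idx = set(groups[chosen])

    new_atoms = []
    for i, a in enumerate(structure.atoms):
        if i in chosen_idx:
            new_atoms.append(replace(a, record_class="ligand"))
        elif a.record_class == "ligand":
            new_atoms.append(replace(a, record_class="other-het"))
        else:
            new_atoms.append(a)
    return Structure(id=structure.id, atoms=new_atoms)


def ligand_molecular_weight(ligand_atoms: Iterable[AtomRecord]) -> float:
    """Sum of standard atomic masses of the atoms present (g/mol).

    No implicit hydrogens are added: PDB HETATM groups usually lack them,
    so this is a heavy-atom-dominated mass.
    """
    total = 0.0
    for a in ligand_atoms:
        el = a.element.upper()
        if el not in ATOMIC_MASSES:
            raise UnknownElementError(f"unknown element {a.element!r}")
        total += ATOMIC_MASSES[el]
    return total


def filter_waters(structure: Structure,
                  ligand_atoms: Optional[Sequence[AtomRecord]] = None,
                  mode: Literal["discard", "retain-near"] = "discard",
                  near_cutoff: float = 5.0) -> Structure:
    """Remove waters, optionally keeping those near the reference ligand.

    mode='discard' removes every water.  mode='retain-near' keeps water
    atoms within ``near_cutoff`` Å of any ligand atom (a point-distance
    simplification of retaining only ordered waters that interact with
    the binding site) and removes the rest.
    """
    if mode == "discard":
        kept = [a for a in structure.atoms if a.record_class != "water"]
        return Structure(id=structure.id, atoms=kept)
    if mode != "retain-near":
        raise ValueError(f"unknown water mode {mode!r}")

    if ligand_atoms is None:
        ligand_atoms = structure.ligand_atoms
    if not ligand_atoms:
        return filter_waters(structure, mode="discard")
    tree = cKDTree(np.vstack([a.pos for a in ligand_atoms]))
    kept = []
    for a in structure.atoms:
        if a.record_class != "water":
            kept.append(a)
            continue
        d, _ = tree.query(a.pos)
        if d <= near_cutoff:
            kept.append(a)
    return Structure(id=structure.id, atoms=kept)


_PDB_LINE = ("{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
             "{seq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
             "{occ:>6.2f}{b:>6.2f}          {el:>2s}\n")


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write the structure back out as a minimal PDB file."""
    with open(path, "w") as fh:
        fh.write(f"REMARK   generated by pockalign: {structure.id}\n")
        for a in structure.atoms:
            rec = "ATOM" if a.record_class == "protein" else "HETATM"
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(_PDB_LINE.format(
                rec=rec, serial=a.serial % 100000, name=name, alt=" ",
                res=a.residue_name[:3], chain=a.chain[:1] or "A",
                seq=a.residue_seq % 10000, icode=" ",
                x=a.pos[0], y=a.pos[1], z=a.pos[2],
                occ=1.0, b=0.0, el=a.element[:2]))
        fh.write("END\n")
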