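"""Library screening: rank template pockets against a query pocket.

Templates are excluded when their global sequence identity to the query
exceeds 40% or their secondary-structure identity exceeds 60% (both strict
">"), since the goal is distant off-targets; survivors are superposed and
scored, then ranked by descending similarity score.

Sequence identity uses Needleman-Wunsch global alignment with BLOSUM62
scores and affine gaps (open 10, extend 0.5); identity is the number of
identical aligned positions divided by the alignment length including
gaps.  Secondary-structure identity is the fraction of aligned (non-gap)
residue pairs sharing the same 3-state class (H/E/C).  DSSP strings may
be supplied externally; a simplified Kabsch-Sander hydrogen-bond assigner
is built in for dependency-free operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (AlignmentError, MissingSecondaryStructureError,
                     UndefinedScoreError)
from .pocket_model import PocketModel, detect_pocket
from .similarity_score import SimilarityScore, score_superposition
from .structure_io import Structure, ligand_molecular_weight
from .superposer import SuperpositionResult, find_best_superposition

logger = logging.getLogger(__name__)

SEQ_IDENTITY_CUTOFF = 0.40   # exclude if strictly greater
SS_IDENTITY_CUTOFF = 0.60    # exclude if strictly greater
MW_WINDOW = (300.0, 800.0)   # g/mol, library build-time ligand filter

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

#: 8-state DSSP → 3-state collapse.
SS_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}

HBOND_ENERGY_CUTOFF = -0.5       # kcal/mol, Kabsch-Sander
_KS_COUPLING = 0.084 * 332.0     # q1*q2*f of the electrostatic model


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _sanitize(seq: str) -> str:
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX")
    return "".join(c if c.upper() in allowed else "X" for c in seq.upper())


def _aligned_columns(a: str, b: str) -> list[tuple[int, int]]:
    """Indices of aligned (non-gap) residue pairs and the alignment length."""
    aln = _aligner().align(_sanitize(a), _sanitize(b))[0]
    pairs = []
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        pairs.extend(zip(range(sa, ea), range(sb, eb)))
    return pairs


def _alignment_length(a: str, b: str, n_aligned: int) -> int:
    # length = aligned columns + unaligned residues of both sequences (gaps)
    return n_aligned + (len(a) - n_aligned) + (len(b) - n_aligned)


def sequence_identity(a: str, b: str) -> float:
    """Global-alignment identity in [0, 1]; gaps count in the length."""
    if not a or not b:
        raise AlignmentError("empty sequence")
    pairs = _aligned_columns(a, b)
    ident = sum(1 for i, j in pairs if a[i].upper() == b[j].upper())
    length = _alignment_length(a, b, len(pairs))
    return ident / length if length else 0.0


def secondary_structure_identity(seq_a: str, ss_a: str,
                                 seq_b: str, ss_b: str) -> float:
    """Fraction of aligned residue pairs with identical 3-state SS class."""
    if not seq_a or not seq_b:
        raise AlignmentError("empty sequence")
    if ss_a is None or ss_b is None:
        raise MissingSecondaryStructureError(
            "secondary-structure strings required: supply DSSP output or "
            "use assign_ss_simplified()")
    if len(ss_a) != len(seq_a) or len(ss_b) != len(seq_b):
        raise MissingSecondaryStructureError(
            "secondary-structure string length must match the sequence")
    col_a = [SS_COLLAPSE.get(c.upper(), "C") for c in ss_a]
    col_b = [SS_COLLAPSE.get(c.upper(), "C") for c in ss_b]
    pairs = _aligned_columns(seq_a, seq_b)
    if not pairs:
        return 0.0
    same = sum(1 for i, j in pairs if col_a[i] == col_b[j])
    return same / len(pairs)


# --- simplified Kabsch-Sander secondary-structure assignment ---------------

def _backbone_by_residue(structure: Structure
                         ) -> list[dict[str, np.ndarray]]:
    residues: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    order: list[tuple[str, int]] = []
    for a in structure.atoms:
        if a.record_class != "protein":
            continue
        key = (a.chain, a.residue_seq)
        if key not in residues:
            residues[key] = {}
            order.append(key)
        if a.name.strip() in ("N", "CA", "C", "O"):
            residues[key][a.name.strip()] = a.pos
    return [residues[k] for k in order]


def _ks_hbond_energy(donor: dict, donor_prev: Optional[dict],
                     acceptor: dict) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol), N-H…O=C."""
    n, o, c = donor.get("N"), acceptor.get("O"), acceptor.get("C")
    if n is None or o is None or c is None:
        return 0.0
    if donor_prev is not None and "C" in donor_prev and "O" in donor_prev:
        co = donor_prev["C"] - donor_prev["O"]
        h = n + co / np.linalg.norm(co)
    else:
        return 0.0  # chain start: no amide H estimate
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0
    return _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_ss_simplified(structure: Structure) -> str:
    """3-state (H/E/C) secondary structure from backbone hydrogen bonds.

    An electrostatic approximation of the Kabsch-Sander energy (cutoff
    −0.5 kcal/mol) defines N-H(i)→O=C(j) hydrogen bonds; i→i+4 turn
    patterns yield helix (H), bridge patterns yield strand (E), the rest
    coil (C).  Residues with missing backbone atoms are classified C.
    """
    res = _backbone_by_residue(structure)
    n = len(res)
    if n == 0:
        raise MissingSecondaryStructureError("no protein residues")
    hbond = np.zeros((n, n), dtype=bool)  # hbond[d, a]: N-H of d to C=O of a
    for d in range(1, n):
        for acc in range(n):
            if abs(d - acc) < 2:
                continue
            e = _ks_hbond_energy(res[d], res[d - 1], res[acc])
            if e < HBOND_ENERGY_CUTOFF:
                hbond[d, acc] = True

    ss = ["C"] * n
    # 4-turns: N-H(i+4) to C=O(i); two consecutive turns make a helix
    turn4 = [i + 4 < n and hbond[i + 4, i] for i in range(n)]
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for j in range(i + 1, min(i + 5, n)):
                ss[j] = "H"
    # bridges (parallel / antiparallel), |i - j| > 2
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = ((hbond[j, i - 1] and hbond[i + 1, j])
                        or (hbond[i, j - 1] and hbond[j + 1, i]))
            anti = ((hbond[i, j] and hbond[j, i])
                    or (hbond[j + 1, i - 1] and hbond[i + 1, j - 1]))
            if parallel or anti:
                for k in (i, j):
                    if ss[k] == "C":
                        ss[k] = "E"
    return "".join(ss)


# --- library records and ranking -------------------------------------------

@dataclass
class TemplateRecord:
    """One library entry: structure, pocket, sequence and SS string."""

    structure_id: str
    ligand_id: str
    pocket: PocketModel
    sequence: str
    ss_string: Optional[str] = None


@dataclass
class RankedHit:
    template_id: str
    score: float
    similarity: SimilarityScore
    superposition: SuperpositionResult
    seq_identity: float
    ss_identity: Optional[float]


def build_template_record(structure: Structure,
                          assign_ss: bool = True,
                          enforce_mw_window: bool = False,
                          **pocket_kwargs) -> TemplateRecord:
    """Detect the pocket of a structure and wrap it as a library record."""
    if enforce_mw_window:
        mw = ligand_molecular_weight(structure.ligand_atoms)
        lo, hi = MW_WINDOW
        if not (lo < mw < hi):
            raise UndefinedScoreError(
                f"{structure.id}: ligand MW {mw:.1f} g/mol outside "
                f"({lo:.0f}, {hi:.0f}) window")
    lig = structure.ligand_atoms
    ligand_id = lig[0].residue_name if lig else ""
    pocket = detect_pocket(structure, **pocket_kwargs)
    ss = assign_ss_simplified(structure) if assign_ss else None
    return TemplateRecord(structure_id=structure.id, ligand_id=ligand_id,
                          pocket=pocket, sequence=structure.sequence,
                          ss_string=ss)


def run_screen(query: TemplateRecord,
               library: Sequence[TemplateRecord],
               seq_cut: float = SEQ_IDENTITY_CUTOFF,
               ss_cut: float = SS_IDENTITY_CUTOFF,
               angle_step: float = 20.0,
               apply_filters: bool = True) -> list[RankedHit]:
    """Filter, superpose, score and rank a template library.

    Templates with seq_identity > seq_cut OR ss_identity > ss_cut are
    dropped (identity filters; values exactly at the cutoff are retained).
    Survivors are superposed against the query pocket and ranked by
    descending score, ties broken by template_id.
    """
    hits: list[RankedHit] = []
    for tmpl in library:
        seq_id = sequence_identity(query.sequence, tmpl.sequence)
        ss_id = None
        if query.ss_string is not None and tmpl.ss_string is not None:
            ss_id = secondary_structure_identity(
                query.sequence, query.ss_string,
                tmpl.sequence, tmpl.ss_string)
        if apply_filters:
            if seq_id > seq_cut:
                logger.info("%s excluded: sequence identity %.2f > %.2f",
                            tmpl.structure_id, seq_id, seq_cut)
                continue
            if ss_id is not None and ss_id > ss_cut:
                logger.info("%s excluded: SS identity %.2f > %.2f",
                            tmpl.structure_id, ss_id, ss_cut)
                continue
        sup = find_best_superposition(query.pocket, tmpl.pocket,
                                      angle_step=angle_step)
        sim = score_superposition(query.pocket, tmpl.pocket, sup.transform)
        hits.append(RankedHit(template_id=tmpl.structure_id,
                              score=sim.score, similarity=sim,
                              superposition=sup, seq_identity=seq_id,
                              ss_identity=ss_id))
    if not hits:
        logger.warning("all templates filtered out; empty rank list")
    hits.sort(key=lambda h: (-h.score, h.template_id))
    return hits
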