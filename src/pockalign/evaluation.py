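"""ROC evaluation of ranked off-target lists against affinity panels.

Two labeling schemes: *ligand-centered* marks a protein a true off-target
when the query structure's co-crystallized ligand binds it strictly below
10 µM; *target-centered* marks it when it shares at least half of the
target's nanomolar (< 1 µM) inhibitors.  Proteins without an affinity
record for the relevant compound(s) are excluded from evaluation rather
than labeled negative (optionally they can be treated as inactive).
ROC AUC is the Mann-Whitney probability that a random positive outscores
a random negative, ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import PockalignError, UndefinedAUCError

LIGAND_CENTERED_THRESHOLD = 1e-5   # molar (10 µM), strict <
NANOMOLAR_THRESHOLD = 1e-6         # molar (1 µM), strict <
SHARE_FRACTION = 0.5               # "at least half", inclusive


@dataclass(frozen=True)
class AffinityRecord:
    """One measured affinity (Kd/Ki/IC50-equivalent, molar)."""

    protein_id: str
    compound_id: str
    affinity: float

    def __post_init__(self) -> None:
        if not self.affinity > 0:
            raise ValueError("affinity must be positive (molar)")


@dataclass
class LabeledRanking:
    """Scored templates with binary off-target labels and the ROC AUC."""

    entries: list[tuple[str, float, int]]  # (template_id, score, label)
    auc: float


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """TSV with columns protein_id, compound_id, affinity_molar."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "compound_id", "affinity_molar"}
    if not required.issubset(df.columns):
        raise PockalignError(
            f"affinity table needs columns {sorted(required)}")
    return [AffinityRecord(str(r.protein_id), str(r.compound_id),
                           float(r.affinity_molar))
            for r in df.itertuples()]


def label_ligand_centered(query_ligand: str,
                          affinities: Iterable[AffinityRecord],
                          threshold: float = LIGAND_CENTERED_THRESHOLD,
                          missing_as_negative: bool = False
                          ) -> dict[str, int]:
    """protein_id → 1 iff the query ligand binds it strictly below threshold.

    Proteins with no record for the query ligand are excluded (absent from
    the map) unless ``missing_as_negative`` is set, in which case callers
    may treat any absent protein as 0.
    """
    records = [r for r in affinities if r.compound_id == query_ligand]
    if not records:
        raise PockalignError(
            f"query ligand {query_ligand!r} absent from the affinity table")
    labels: dict[str, int] = {}
    for r in records:
        labels[r.protein_id] = max(labels.get(r.protein_id, 0),
                                   int(r.affinity < threshold))
    return labels


def label_target_centered(target_id: str,
                          affinities: Iterable[AffinityRecord],
                          nm_threshold: float = NANOMOLAR_THRESHOLD,
                          share_fraction: float = SHARE_FRACTION,
                          denominator: str = "target") -> dict[str, int]:
    """protein_id → 1 iff it shares enough of the target's nM inhibitors.

    S_t = compounds binding the target strictly below ``nm_threshold``;
    S_p likewise per candidate protein.  Label 1 iff
    |S_t ∩ S_p| / denom ≥ share_fraction with denom = |S_t| by default
    ("target"); alternatives: "candidate" (|S_p|), "min", "union".
    """
    nm: dict[str, set[str]] = {}
    for r in affinities:
        if r.affinity < nm_threshold:
            nm.setdefault(r.protein_id, set()).add(r.compound_id)
    s_t = nm.get(target_id, set())
    if not s_t:
        raise PockalignError(
            f"target {target_id!r} has no inhibitor below "
            f"{nm_threshold:g} M")
    labels: dict[str, int] = {}
    for pid, s_p in nm.items():
        inter = len(s_t & s_p)
        denom = {"target": len(s_t), "candidate": len(s_p),
                 "min": min(len(s_t), len(s_p)),
                 "union": len(s_t | s_p)}[denominator]
        labels[pid] = int(denom > 0 and inter / denom >= share_fraction)
    return labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score⁺ > score⁻) + ½ P(score⁺ = score⁻)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined with {n_pos} positives / {n_neg} negatives")
    ranks = rankdata(scores)  # average ranks handle ties as ½
    u = float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_curve_points(scores: Sequence[float], labels: Sequence[int]
                     ) -> np.ndarray:
    """(FPR, TPR) points of the ROC curve, thresholds descending."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    # collapse tied thresholds to their last point
    keep = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[keep] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[keep] / max(fps[-1], 1)]
    return np.column_stack([fpr, tpr])


def evaluate_ranking(template_scores: dict[str, float],
                     labels: dict[str, int],
                     missing_as_negative: bool = False) -> LabeledRanking:
    """Join a score map with a label map and compute the ROC AUC.

    Templates without a label are excluded unless ``missing_as_negative``.
    """
    entries = []
    for tid, score in sorted(template_scores.items(),
                             key=lambda kv: (-kv[1], kv[0])):
        if tid in labels:
            entries.append((tid, score, labels[tid]))
        elif missing_as_negative:
            entries.append((tid, score, 0))
    if not entries:
        raise UndefinedAUCError("no scored template carries a label")
    auc = roc_auc([e[1] for e in entries], [e[2] for e in entries])
    return LabeledRanking(entries=entries, auc=auc)
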