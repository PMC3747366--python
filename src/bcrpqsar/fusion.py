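"""Two-model ensembles by simple data fusion.

A polyspecific transporter (multiple binding sites) defeats any single
linear discriminant; a pair of discriminants fused per compound by the
elementwise maximum (MAX) or average (AVE) of their scores can express
an OR-of-half-spaces decision region.  All C(n, 2) model pairs are
enumerated and ranked primarily by ascending false-positive count on
the external test set (a false positive = a compound predicted
nonsubstrate that is actually a substrate — the costly error when the
goal is discarding substrates), with ties broken by descending
high-specificity partial AUC, then descending total AUC, then pair
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .io import NONSUBSTRATE, SUBSTRATE
from .roc import ScoredRanking, _pauc_from_curve, empirical_roc

OPERATORS = ("MAX", "AVE")


def fuse_scores(scores_a: np.ndarray, scores_b: np.ndarray, operator: str) -> np.ndarray:
    """Elementwise MAX or AVE of two aligned score vectors."""
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must have the same length")
    if operator == "MAX":
        return np.maximum(scores_a, scores_b)
    if operator == "AVE":
        return (scores_a + scores_b) / 2.0
    raise ValueError(f"unknown fusion operator {operator!r}")


@dataclass
class EnsembleCandidate:
    """One evaluated 2-model combination."""

    index_a: int
    index_b: int
    operator: str
    fp_count: int
    pauc: float
    auc: float

    @property
    def sort_key(self) -> tuple:
        return (self.fp_count, -self.pauc, -self.auc, self.index_a, self.index_b,
                self.operator)


def _screening_ranking(ids: list[str], df: np.ndarray, labels: np.ndarray) -> ScoredRanking:
    """Hits = nonsubstrates, ranked by ascending discriminant value."""
    return ScoredRanking(
        ids=ids, scores=df, is_hit=labels == NONSUBSTRATE,
        higher_score_is_hit=False, hit_definition="nonsubstrate_is_hit",
    )


def evaluate_fused(
    ids: list[str],
    fused_df: np.ndarray,
    labels: np.ndarray,
    sp_lo: float = 0.7,
    threshold: float = 0.0,
) -> tuple[int, float, float]:
    """FP count at the fixed threshold, high-Sp pAUC, and total AUC."""
    call_nonsub = fused_df <= threshold  # df == threshold -> nonsubstrate
    fp = int((call_nonsub & (labels == SUBSTRATE)).sum())
    curve = empirical_roc(_screening_ranking(ids, fused_df, labels))
    pauc = _pauc_from_curve(curve.fpr, curve.tpr, 1 - sp_lo)
    return fp, pauc, curve.auc


def enumerate_ensembles(
    score_matrix: np.ndarray,
    labels: np.ndarray,
    ids: Sequence[str] | None = None,
    operators: Sequence[str] = OPERATORS,
    sp_lo: float = 0.7,
) -> list[EnsembleCandidate]:
    """Score every 2-model combination under every fusion operator.

    Parameters
    ----------
    score_matrix
        (n_models, n_compounds) discriminant values on the evaluation set.
    labels
        +/-1 class labels of the evaluation compounds.
    """
    score_matrix = np.asarray(score_matrix, dtype=np.float64)
    labels = np.asarray(labels)
    n_models = score_matrix.shape[0]
    if n_models < 2:
        raise ValueError("need at least 2 models to form ensembles")
    if ids is None:
        ids = [f"c{i}" for i in range(score_matrix.shape[1])]
    ids = list(ids)

    candidates: list[EnsembleCandidate] = []
    for a, b in combinations(range(n_models), 2):
        for op in operators:
            fused = fuse_scores(score_matrix[a], score_matrix[b], op)
            fp, pauc, auc = evaluate_fused(ids, fused, labels, sp_lo=sp_lo)
            candidates.append(EnsembleCandidate(a, b, op, fp, pauc, auc))
    candidates.sort(key=lambda c: c.sort_key)
    return candidates


def best_ensemble(candidates: list[EnsembleCandidate]) -> EnsembleCandidate:
    if not candidates:
        raise ValueError("no ensemble candidates")
    return candidates[0]


def leaderboard_rows(candidates: list[EnsembleCandidate]) -> list[dict]:
    return [
        {
            "rank": i + 1, "model_a": c.index_a, "model_b": c.index_b,
            "operator": c.operator, "fp_test": c.fp_count,
            "pauc_highsp": c.pauc, "auc": c.auc,
        }
        for i, c in enumerate(candidates)
    ]
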