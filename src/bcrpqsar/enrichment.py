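"""Early-recognition metrics and the simulated virtual-screening campaign.

Metrics for the early-recognition problem — does the scoring function
rank the hits at the top of a large library? —:

* AUCc, the area under the accumulation curve (fraction of hits found
  vs fraction of library screened).  It satisfies the exact identity
  ``ROC AUC = AUCc / R_i - R_a / (2 R_i)`` with R_a = A/N the hit
  ratio and R_i = 1 - R_a, because the screened fraction is the
  R_a/R_i-weighted mixture of Se and 1-Sp.
* EF, the enrichment factor at a selection fraction x: the hit rate in
  the top n = floor(x N) compounds relative to the library hit rate.
* RIE and BEDROC, exponentially rank-weighted metrics (weight
  exp(-alpha r / N)); RIE has random expectation 1, BEDROC is RIE
  rescaled to [0, 1].

The screening campaign disperses the external test set among decoys
(putative substrates counted as non-hits), ranks by ascending
discriminant value with hits = known nonsubstrates, and reports all
four metrics; a saturation caveat is logged when the hit ratio is high
enough (> 0.2) that early-recognition metrics lose resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import NONSUBSTRATE, SUBSTRATE, CompoundRecord, DescriptorMatrix
from .roc import ScoredRanking, empirical_roc

logger = logging.getLogger(__name__)

SATURATION_HIT_RATIO = 0.2


def accumulation_auc(ranking: ScoredRanking) -> float:
    """Trapezoid area under the accumulation curve.

    The curve is swept over the observed score cuts (like the empirical
    ROC, so tied scores form straight segments): x = fraction of the
    library at or above the cut, y = fraction of hits at or above the
    cut.  Computed this way the AUCc<->ROC-AUC identity holds to
    machine precision on every ranking, ties included.
    """
    ranking.check_roc_ready()
    curve = empirical_roc(ranking)
    ra = ranking.n_hits / len(ranking.scores)
    frac_screened = ra * curve.tpr + (1 - ra) * curve.fpr
    return float(np.trapezoid(curve.tpr, frac_screened))


def roc_auc_from_aucc(aucc: float, r_a: float) -> float:
    """Invert the identity ROC AUC = AUCc/R_i - R_a/(2 R_i)."""
    r_i = 1 - r_a
    return aucc / r_i - r_a / (2 * r_i)


def enrichment_factor(ranking: ScoredRanking, x: float = 0.10, n_select: int | None = None) -> float:
    """EF = (hits in top n / n) / (A / N), with n = floor(x N).

    ``n_select`` overrides the fraction with an explicit selection size
    (conventions differ between reports; the one used is always stated
    in output).
    """
    ranking.check_roc_ready()
    n_total = len(ranking.scores)
    a = ranking.n_hits
    if n_select is None:
        if not 0 < x <= 1:
            raise ValueError("selection fraction x must lie in (0, 1]")
        n_select = int(np.floor(x * n_total))
    if n_select <= 0:
        raise ValueError("selection is empty; increase x")
    order = ranking.order()
    hits_in_sel = int(ranking.is_hit[order[:n_select]].sum())
    return (hits_in_sel / n_select) / (a / n_total)


def rie(ranking: ScoredRanking, alpha: float = 20.0) -> float:
    """Robust initial enhancement.

    RIE = (1/A) sum_hits exp(-alpha r_i / N) divided by its value for a
    uniformly random ranking, (1/N)(1 - e^-alpha)/(e^(alpha/N) - 1).
    Ranks r_i are 1-based positions in the best-first ordering.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    ranking.check_roc_ready()
    n = len(ranking.scores)
    order = ranking.order()
    ranks = np.flatnonzero(ranking.is_hit[order]) + 1
    a = ranking.n_hits
    numerator = np.exp(-alpha * ranks / n).sum() / a
    denominator = (1.0 / n) * (1 - np.exp(-alpha)) / (np.exp(alpha / n) - 1)
    return float(numerator / denominator)


def bedroc(ranking: ScoredRanking, alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC: RIE rescaled to [0, 1]."""
    ranking.check_roc_ready()
    n = len(ranking.scores)
    r_a = ranking.n_hits / n
    rie_val = rie(ranking, alpha)
    scale = r_a * np.sinh(alpha / 2) / (np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * r_a))
    return float(rie_val * scale + 1.0 / (1 - np.exp(alpha * (1 - r_a))))


@dataclass
class EnrichmentReport:
    """All early-recognition metrics for one ranked library."""

    n_library: int
    n_hits: int
    aucc: float
    roc_auc: float
    ef: float
    ef_fraction: float
    ef_n_selected: int
    rie: float
    bedroc: float
    alpha: float
    hit_definition: str
    saturated: bool

    @property
    def r_a(self) -> float:
        return self.n_hits / self.n_library

    @property
    def r_i(self) -> float:
        return 1 - self.r_a

    def as_dict(self) -> dict:
        return {
            "N": self.n_library, "A": self.n_hits,
            "R_a": self.r_a, "R_i": self.r_i,
            "AUCc": self.aucc, "ROC_AUC": self.roc_auc,
            "EF": self.ef, "EF_fraction": self.ef_fraction,
            "EF_n_selected": self.ef_n_selected,
            "RIE": self.rie, "BEDROC": self.bedroc, "alpha": self.alpha,
            "hit_definition": self.hit_definition, "saturated": self.saturated,
        }

    def text_table(self) -> str:
        return "\n".join([
            f"library size N = {self.n_library}, hits A = {self.n_hits} "
            f"(R_a = {self.r_a:.4f}; hits: {self.hit_definition})",
            f"Accumulation curve AUC (AUCc)   {self.aucc:.4f}",
            f"ROC AUC (identity from AUCc)    {self.roc_auc:.4f}",
            f"Enrichment factor (EF)          {self.ef:.4f}"
            f"  (top {self.ef_n_selected} = {self.ef_fraction:.1%} of library)",
            f"Robust initial enhancement (RIE) {self.rie:.4f}  (alpha = {self.alpha:g})",
            f"BEDROC                          {self.bedroc:.4f}  (alpha = {self.alpha:g})",
        ] + (["WARNING: hit ratio > 0.2 -- saturation effect, early-recognition "
              "metrics are compressed"] if self.saturated else []))


def enrichment_report(
    ranking: ScoredRanking,
    alpha: float = 20.0,
    ef_fraction: float = 0.10,
    ef_n_select: int | None = None,
) -> EnrichmentReport:
    n = len(ranking.scores)
    aucc = accumulation_auc(ranking)
    r_a = ranking.n_hits / n
    n_sel = ef_n_select if ef_n_select is not None else int(np.floor(ef_fraction * n))
    saturated = r_a > SATURATION_HIT_RATIO
    if saturated:
        logger.warning(
            "hit ratio %.3f exceeds %.1f: saturation effect, early-recognition "
            "metrics lose resolution", r_a, SATURATION_HIT_RATIO,
        )
    return EnrichmentReport(
        n_library=n, n_hits=ranking.n_hits,
        aucc=aucc, roc_auc=roc_auc_from_aucc(aucc, r_a),
        ef=enrichment_factor(ranking, n_select=n_sel),
        ef_fraction=n_sel / n, ef_n_selected=n_sel,
        rie=rie(ranking, alpha), bedroc=bedroc(ranking, alpha),
        alpha=alpha, hit_definition=ranking.hit_definition,
        saturated=saturated,
    )


def run_screening_campaign(
    score_fn,
    library_records: list[CompoundRecord],
    library_matrix: DescriptorMatrix,
    alpha: float = 20.0,
    ef_fraction: float = 0.10,
) -> tuple[EnrichmentReport, ScoredRanking]:
    """Score a decoy-spiked library and compute early-recognition metrics.

    ``score_fn`` maps a DescriptorMatrix to discriminant values (an
    individual model's ``.score`` or a fused-ensemble scorer).  Hits are
    the *known* nonsubstrates; decoys (putative substrates) count as
    non-hits even though some may actually be nonsubstrates, so the
    reported performance is conservative.  The library is ranked by
    ascending discriminant value (most nonsubstrate-like first).
    """
    ids = [r.id for r in library_records]
    matrix = library_matrix.subset_compounds(ids)
    is_hit = np.array(
        [r.label == NONSUBSTRATE and r.provenance == "known" for r in library_records]
    )
    if not is_hit.any():
        raise ValueError("screening library contains no known nonsubstrates")
    df = np.asarray(score_fn(matrix), dtype=np.float64)
    ranking = ScoredRanking(
        ids=ids, scores=df, is_hit=is_hit,
        higher_score_is_hit=False, hit_definition="nonsubstrate_is_hit",
    )
    return enrichment_report(ranking, alpha=alpha, ef_fraction=ef_fraction), ranking
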