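"""Nonparametric ROC machinery.

Empirical ROC curves (one point per observed cut, ties producing
diagonal segments), trapezoid AUC with its Mann-Whitney placement-value
(DeLong-type) variance and covariance, a paired two-sample z-test for
comparing AUCs of curves built on the same compounds, unnormalized
partial AUC over a high-specificity band with stratified bootstrap, and
score-threshold optimization.

Orientation: a :class:`ScoredRanking` carries binary *hit* labels and a
``higher_score_is_hit`` flag; scores are sign-normalized internally so
that, after normalization, larger scores are more hit-like.  In a
screening context the hits are the known nonsubstrates ranked by
ascending discriminant value (most negative first), and reports always
state which orientation was used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .validation import ConfusionSummary


@dataclass
class ScoredRanking:
    """Ordered scores with binary hit labels for ROC / enrichment work."""

    ids: list[str]
    scores: np.ndarray
    is_hit: np.ndarray
    higher_score_is_hit: bool = True
    hit_definition: str = "substrate_is_hit"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.is_hit = np.asarray(self.is_hit, dtype=bool)
        if len(self.scores) != len(self.is_hit) or len(self.scores) != len(self.ids):
            raise ValueError("ids, scores and labels must be aligned")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @property
    def oriented_scores(self) -> np.ndarray:
        """Scores sign-normalized so higher means more hit-like."""
        return self.scores if self.higher_score_is_hit else -self.scores

    @property
    def n_hits(self) -> int:
        return int(self.is_hit.sum())

    @property
    def n_nonhits(self) -> int:
        return int((~self.is_hit).sum())

    def check_roc_ready(self) -> None:
        if self.n_hits == 0 or self.n_nonhits == 0:
            raise ValueError("ROC requires at least one hit and one non-hit")

    def order(self) -> np.ndarray:
        """Indices sorting compounds best-first (stable for ties)."""
        return np.argsort(-self.oriented_scores, kind="stable")


@dataclass
class ROCCurve:
    fpr: np.ndarray  # 1 - Sp at each observed cut
    tpr: np.ndarray  # Se at each observed cut
    auc: float
    variance: float
    n_hits: int
    n_nonhits: int

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _placements(ranking: ScoredRanking) -> tuple[np.ndarray, np.ndarray]:
    """Placement values V10 (per hit) and V01 (per non-hit), ties at 1/2."""
    y = ranking.oriented_scores
    hits, nonhits = y[ranking.is_hit], y[~ranking.is_hit]
    # midranks over the combined sample give the placements in O(n log n)
    combined = np.concatenate([hits, nonhits])
    mid = stats.rankdata(combined, method="average")
    rank_h = stats.rankdata(hits, method="average")
    rank_n = stats.rankdata(nonhits, method="average")
    m, n = len(hits), len(nonhits)
    v10 = (mid[:m] - rank_h) / n           # P(hit > non-hit) per hit
    v01 = 1.0 - (mid[m:] - rank_n) / m     # per non-hit
    return v10, v01


def empirical_roc(ranking: ScoredRanking) -> ROCCurve:
    """Empirical ROC curve with trapezoid AUC and Mann-Whitney variance."""
    ranking.check_roc_ready()
    y = ranking.oriented_scores
    if np.ptp(y) == 0:
        warnings.warn("all scores identical: ROC is the chance diagonal", stacklevel=2)
        fpr, tpr = np.array([0.0, 1.0]), np.array([0.0, 1.0])
    else:
        fpr, tpr, _ = _sk_roc_curve(ranking.is_hit.astype(int), y, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    v10, v01 = _placements(ranking)
    m, n = ranking.n_hits, ranking.n_nonhits
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) + (v01.var(ddof=1) / n if n > 1 else 0.0)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc, variance=float(var),
                    n_hits=m, n_nonhits=n)


def auc_variance_covariance(
    ranking_a: ScoredRanking, ranking_b: ScoredRanking
) -> tuple[float, float, float]:
    """DeLong placement-value Var(AUC_A), Var(AUC_B), Covar(AUC_A, AUC_B).

    The two rankings must score the same compounds with the same hit
    labels (paired curves).
    """
    if ranking_a.ids != ranking_b.ids or not np.array_equal(
        ranking_a.is_hit, ranking_b.is_hit
    ):
        raise ValueError("paired AUC comparison requires identical compounds and labels")
    va10, va01 = _placements(ranking_a)
    vb10, vb01 = _placements(ranking_b)
    m, n = ranking_a.n_hits, ranking_a.n_nonhits
    s10 = np.cov(va10, vb10, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(va01, vb01, ddof=1) if n > 1 else np.zeros((2, 2))
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    covar = s10[0, 1] / m + s01[0, 1] / n
    return float(var_a), float(var_b), float(covar)


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    covar_ab: float
    z: float
    p_value: float


def compare_auc(ranking_a: ScoredRanking, ranking_b: ScoredRanking) -> AUCComparison:
    """Paired z-test of AUC_A = AUC_B for curves built on the same sample.

    z = (AUC_A - AUC_B) / sqrt(Var_A + Var_B - 2 Covar_AB), two-sided
    normal p-value.  Identical curves report z = 0, p = 1.
    """
    auc_a = empirical_roc(ranking_a).auc
    auc_b = empirical_roc(ranking_b).auc
    var_a, var_b, covar = auc_variance_covariance(ranking_a, ranking_b)
    denom_sq = var_a + var_b - 2 * covar
    diff = auc_a - auc_b
    if denom_sq <= 1e-16:
        if abs(diff) > 1e-12:
            raise ValueError("zero comparison variance but unequal AUCs: inconsistent inputs")
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(denom_sq)
        p = 2 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a, auc_b, var_a, var_b, covar, float(z), float(p))


# ----------------------------------------------------------------------
# Partial AUC over a specificity band
# ----------------------------------------------------------------------

@dataclass
class PAUCResult:
    sp_lo: float
    pauc: float                 # unnormalized trapezoid area over Sp in [sp_lo, 1]
    bootstrap_sd: float
    ci_low: float
    ci_high: float
    n_boot: int
    normalized: float = field(init=False)

    def __post_init__(self) -> None:
        width = 1 - self.sp_lo
        self.normalized = self.pauc / width if width > 0 else 0.0


def _pauc_from_curve(fpr: np.ndarray, tpr: np.ndarray, x_max: float) -> float:
    """Trapezoid area of the ROC over fpr in [0, x_max] (= Sp in [sp_lo, 1])."""
    if x_max <= 0:
        return 0.0
    xs = np.clip(fpr, 0, x_max)
    if fpr[-1] > x_max:  # interpolate the curve at the band edge
        ys = np.interp(xs, fpr, tpr)
    else:
        ys = tpr
    return float(np.trapezoid(ys, xs))


def partial_auc(
    ranking: ScoredRanking,
    sp_lo: float = 0.7,
    n_boot: int = 2000,
    seed: int = 0,
) -> PAUCResult:
    """Unnormalized pAUC over Sp in [sp_lo, 1] with stratified bootstrap.

    Each bootstrap replicate resamples hits and non-hits separately,
    preserving the original group sizes exactly; SD and percentile
    95% CI come from the replicate distribution.
    """
    if not 0 <= sp_lo <= 1:
        raise ValueError("sp_lo must lie in [0, 1]")
    ranking.check_roc_ready()
    if 0 < n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap estimates will be unstable", stacklevel=2)
    x_max = 1 - sp_lo
    curve = empirical_roc(ranking)
    point = _pauc_from_curve(curve.fpr, curve.tpr, x_max)

    y = ranking.oriented_scores
    hits, nonhits = y[ranking.is_hit], y[~ranking.is_hit]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        hs = rng.choice(hits, size=len(hits), replace=True)
        ns = rng.choice(nonhits, size=len(nonhits), replace=True)
        scores = np.concatenate([hs, ns])
        labels = np.concatenate([np.ones(len(hs), bool), np.zeros(len(ns), bool)])
        if np.ptp(scores) == 0:
            fpr = tpr = np.array([0.0, 1.0])
        else:
            fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
        reps[b] = _pauc_from_curve(fpr, tpr, x_max)
    if n_boot:
        sd = float(reps.std(ddof=1)) if n_boot > 1 else 0.0
        lo, hi = (float(v) for v in np.percentile(reps, [2.5, 97.5]))
    else:
        sd, lo, hi = 0.0, point, point
    return PAUCResult(sp_lo=sp_lo, pauc=point, bootstrap_sd=sd,
                      ci_low=lo, ci_high=hi, n_boot=n_boot)


def compare_pauc(
    ranking_a: ScoredRanking,
    ranking_b: ScoredRanking,
    sp_lo: float = 0.7,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Paired stratified-bootstrap test of pAUC_A = pAUC_B.

    Resamples compound indices (hits and non-hits separately), scores
    both curves on each replicate, and reports the bootstrap p-value of
    the paired difference (fraction of replicate differences crossing 0,
    doubled and clipped).
    """
    if ranking_a.ids != ranking_b.ids or not np.array_equal(
        ranking_a.is_hit, ranking_b.is_hit
    ):
        raise ValueError("paired pAUC comparison requires identical compounds and labels")
    x_max = 1 - sp_lo
    a_curve = empirical_roc(ranking_a)
    b_curve = empirical_roc(ranking_b)
    point_a = _pauc_from_curve(a_curve.fpr, a_curve.tpr, x_max)
    point_b = _pauc_from_curve(b_curve.fpr, b_curve.tpr, x_max)

    hit_idx = np.flatnonzero(ranking_a.is_hit)
    non_idx = np.flatnonzero(~ranking_a.is_hit)
    ya, yb = ranking_a.oriented_scores, ranking_b.oriented_scores
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    labels = np.concatenate([np.ones(len(hit_idx), int), np.zeros(len(non_idx), int)])
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(hit_idx, size=len(hit_idx), replace=True),
            rng.choice(non_idx, size=len(non_idx), replace=True),
        ])
        vals = []
        for y in (ya, yb):
            s = y[idx]
            if np.ptp(s) == 0:
                fpr = tpr = np.array([0.0, 1.0])
            else:
                fpr, tpr, _ = _sk_roc_curve(labels, s, drop_intermediate=False)
            vals.append(_pauc_from_curve(fpr, tpr, x_max))
        diffs[b] = vals[0] - vals[1]
    observed = point_a - point_b
    crossing = float(np.mean(diffs <= 0)) if observed > 0 else float(np.mean(diffs >= 0))
    p = min(1.0, 2 * crossing)
    return {
        "pauc_a": point_a, "pauc_b": point_b, "difference": observed,
        "p_value": p, "n_boot": n_boot, "sp_lo": sp_lo,
    }


# ----------------------------------------------------------------------
# Threshold optimization
# ----------------------------------------------------------------------

def optimize_threshold(
    ranking: ScoredRanking,
    criterion: str = "youden",
    floor: float | None = None,
) -> tuple[float, ConfusionSummary]:
    """Pick a score threshold among the observed cuts.

    criterion:
      - ``"youden"``: maximize Se + Sp - 1;
      - ``"se_at_sp"``: maximize Se subject to Sp >= floor;
      - ``"sp_at_se"``: maximize Sp subject to Se >= floor.
    Ties are broken toward higher Sp (the conservative choice when the
    cost of a false positive dominates).
    """
    ranking.check_roc_ready()
    y = ranking.oriented_scores
    hits = ranking.is_hit
    cuts = np.unique(y)
    # thresholds midway between consecutive observed scores, plus ends
    thresholds = np.concatenate([[cuts[0] - 1.0], (cuts[:-1] + cuts[1:]) / 2, [cuts[-1] + 1.0]])

    best: tuple | None = None
    for thr in thresholds:
        call_hit = y > thr
        tp = int((call_hit & hits).sum())
        fp = int((call_hit & ~hits).sum())
        tn = int((~call_hit & ~hits).sum())
        fn = int((~call_hit & hits).sum())
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        if criterion == "youden":
            key = (se + sp - 1, sp)
        elif criterion == "se_at_sp":
            if floor is None:
                raise ValueError("se_at_sp requires a Sp floor")
            if sp < floor:
                continue
            key = (se, sp)
        elif criterion == "sp_at_se":
            if floor is None:
                raise ValueError("sp_at_se requires a Se floor")
            if se < floor:
                continue
            key = (sp, se)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        cand = (key, thr, ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn,
                                           positive_class=ranking.hit_definition))
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        # report best attainable constraint value for the error message
        attainable = []
        for thr in thresholds:
            call_hit = y > thr
            se = (call_hit & hits).sum() / hits.sum()
            sp = (~call_hit & ~hits).sum() / (~hits).sum()
            attainable.append(sp if criterion == "se_at_sp" else se)
        raise ValueError(
            f"floor {floor} infeasible; best attainable is {max(attainable):.3f}"
        )
    return float(best[1]), best[2]
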