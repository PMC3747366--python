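"""Random-subspace discriminant models.

One individual classifier is built in three stages:

1. a *descriptor pool* — a random combination of descriptor blocks
   whose total size falls near a target (around 200 descriptors), the
   random-subspace device that decorrelates the ensemble members;
2. stepwise forward selection on the +/-1 class dummy by multiple
   linear regression, guarded by an F-to-enter significance level, a
   collinearity tolerance floor (1 - R^2 of the candidate on the
   already-selected descriptors) and a minimum cases-to-predictors
   ratio;
3. a pooled-covariance two-class linear discriminant fit on the
   selected descriptors, oriented so substrates score positive.

The discriminant function is ``df = a0 + sum_i a_i * d_i``; a compound
is called a substrate when df exceeds the threshold (0 by default,
with ties going to nonsubstrate — the conservative call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import NONSUBSTRATE, SUBSTRATE, DescriptorMatrix

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Descriptor pools
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorPool:
    pool_id: int
    block_names: tuple[str, ...]
    descriptor_names: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.descriptor_names)


def generate_pools(
    blocks: dict[str, list[str]],
    n_pools: int,
    target_size: int = 200,
    seed: int = 0,
    band: float = 0.2,
) -> list[DescriptorPool]:
    """Draw random block combinations with sizes in [1-band, 1+band]*target.

    Combinations are drawn without repetition while distinct feasible
    combinations remain; duplicates are allowed only once the feasible
    set is exhausted.
    """
    if len(blocks) < 2:
        raise ValueError("need at least 2 descriptor blocks")
    names = sorted(blocks)
    sizes = {b: len(blocks[b]) for b in names}
    lo, hi = (1 - band) * target_size, (1 + band) * target_size

    feasible: list[tuple[str, ...]] = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            if lo <= sum(sizes[b] for b in combo) <= hi:
                feasible.append(combo)
    if not feasible:
        totals = [sum(sizes[b] for b in c) for r in range(1, len(names) + 1)
                  for c in combinations(names, r)]
        raise ValueError(
            f"no block combination reaches [{lo:.0f}, {hi:.0f}] descriptors; "
            f"feasible totals span [{min(totals)}, {max(totals)}]"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(feasible))
    pools: list[DescriptorPool] = []
    for i in range(n_pools):
        if i < len(feasible):
            combo = feasible[order[i]]
        else:  # uniqueness impossible: reuse with replacement
            combo = feasible[rng.integers(len(feasible))]
        descs = tuple(n for b in combo for n in blocks[b])
        pools.append(DescriptorPool(pool_id=i, block_names=combo, descriptor_names=descs))
    return pools


# ----------------------------------------------------------------------
# Stepwise forward selection (MLR on the +/-1 dummy)
# ----------------------------------------------------------------------

@dataclass
class SelectionConfig:
    tolerance_min: float = 0.1
    max_steps: int = 10
    alpha_enter: float = 0.05
    min_cases_per_predictor: int = 11

    def __post_init__(self) -> None:
        if not 0 < self.tolerance_min <= 1:
            raise ValueError("tolerance_min must lie in (0, 1]")
        if not 0 < self.alpha_enter < 1:
            raise ValueError("alpha_enter must lie in (0, 1)")


def stepwise_select(
    x: pd.DataFrame, labels: np.ndarray, config: SelectionConfig
) -> list[str]:
    """Forward selection of descriptors regressing the +/-1 class dummy.

    At each step the candidate with the largest F-to-enter among those
    with entry p-value < alpha_enter and tolerance >= tolerance_min is
    added; ties are broken by descriptor name.  Stops when no candidate
    qualifies, max_steps is reached, or adding a descriptor would drop
    the cases-to-predictors ratio below the floor.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if not set(np.unique(labels)) <= {SUBSTRATE, NONSUBSTRATE}:
        raise ValueError("labels must be +1/-1")
    n = len(labels)
    names = list(x.columns)
    arr = x.to_numpy(dtype=np.float64)

    variances = arr.var(axis=0)
    usable = variances > 0
    if (~usable).any():
        logger.info("stepwise_select: skipping %d zero-variance descriptors",
                    int((~usable).sum()))

    selected: list[int] = []
    # Orthonormal basis of span(1, selected descriptors), grown by
    # Gram-Schmidt so each step is O(n * n_candidates).
    q = np.ones((n, 1)) / np.sqrt(n)
    y_perp = labels - q @ (q.T @ labels)

    for _ in range(config.max_steps):
        k = len(selected)
        if n / (k + 1) < config.min_cases_per_predictor:
            break
        df2 = n - k - 2  # residual dof after adding one more predictor
        if df2 <= 0:
            break
        rss0 = float(y_perp @ y_perp)

        cand = [j for j in range(len(names)) if usable[j] and j not in selected]
        if not cand:
            break
        xc = arr[:, cand]
        xc_perp = xc - q @ (q.T @ xc)
        perp_ss = np.einsum("ij,ij->j", xc_perp, xc_perp)
        centered = xc - xc.mean(axis=0)
        total_ss = np.einsum("ij,ij->j", centered, centered)
        with np.errstate(divide="ignore", invalid="ignore"):
            tolerance = np.where(total_ss > 0, perp_ss / total_ss, 0.0)
            reduction = np.where(perp_ss > 1e-12, (xc_perp.T @ y_perp) ** 2 / perp_ss, 0.0)
            rss1 = rss0 - reduction
            f_enter = np.where(rss1 > 1e-12, reduction / (rss1 / df2), np.inf)
        p_enter = stats.f.sf(f_enter, 1, df2)

        ok = (p_enter < config.alpha_enter) & (tolerance >= config.tolerance_min)
        ok &= perp_ss > 1e-10
        if not ok.any():
            break
        best_f = f_enter[ok].max()
        tied = [cand[i] for i in np.flatnonzero(ok) if f_enter[i] >= best_f * (1 - 1e-12)]
        j = min(tied, key=lambda idx: names[idx])

        selected.append(j)
        jj = cand.index(j)
        q_new = xc_perp[:, jj] / np.sqrt(perp_ss[jj])
        q = np.hstack([q, q_new[:, None]])
        y_perp = y_perp - q_new * (q_new @ labels)

    return [names[j] for j in selected]


# ----------------------------------------------------------------------
# Linear discriminant fit and scoring
# ----------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """One fitted discriminant function df = a0 + sum_i a_i * d_i."""

    descriptors: list[str]
    coefficients: np.ndarray
    intercept: float
    pool_id: int | None = None
    f_statistic: float = np.nan
    p_value: float = np.nan
    tolerances: dict[str, float] = field(default_factory=dict)
    config: SelectionConfig | None = None
    n_train: int = 0

    @property
    def cases_per_predictor(self) -> float:
        return self.n_train / len(self.descriptors)

    def score(self, matrix: DescriptorMatrix | pd.DataFrame) -> np.ndarray:
        """Discriminant-function values for the given compounds."""
        values = matrix.values if isinstance(matrix, DescriptorMatrix) else matrix
        missing = [d for d in self.descriptors if d not in values.columns]
        if missing:
            raise ValueError(f"matrix lacks model descriptors: {missing}")
        x = values[self.descriptors].to_numpy(dtype=np.float64)
        return self.intercept + x @ self.coefficients

    def classify(self, matrix: DescriptorMatrix | pd.DataFrame, threshold: float = 0.0) -> np.ndarray:
        """Class calls: substrate iff df > threshold (df == threshold -> nonsubstrate)."""
        df = self.score(matrix)
        return np.where(df > threshold, SUBSTRATE, NONSUBSTRATE)

    def to_dict(self) -> dict:
        return {
            "descriptors": self.descriptors,
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "pool_id": self.pool_id,
            "f_statistic": float(self.f_statistic),
            "p_value": float(self.p_value),
            "tolerances": {k: float(v) for k, v in self.tolerances.items()},
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminantModel":
        return cls(
            descriptors=list(d["descriptors"]),
            coefficients=np.asarray(d["coefficients"], dtype=np.float64),
            intercept=float(d["intercept"]),
            pool_id=d.get("pool_id"),
            f_statistic=float(d.get("f_statistic", np.nan)),
            p_value=float(d.get("p_value", np.nan)),
            tolerances=d.get("tolerances", {}),
            n_train=int(d.get("n_train", 0)),
        )


def _regression_fit_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Overall F and p of the MLR of the dummy on the selected descriptors."""
    n, k = x.shape
    design = np.hstack([np.ones((n, 1)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df2 = n - k - 1
    if df2 <= 0 or rss <= 1e-12 or tss <= rss:
        return np.inf, 0.0
    f = ((tss - rss) / k) / (rss / df2)
    return f, float(stats.f.sf(f, k, df2))


def _tolerances(x: np.ndarray, names: Sequence[str]) -> dict[str, float]:
    out = {}
    n, k = x.shape
    for j, name in enumerate(names):
        if k == 1:
            out[name] = 1.0
            continue
        others = np.hstack([np.ones((n, 1)), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
        resid = x[:, j] - others @ beta
        tss = float(((x[:, j] - x[:, j].mean()) ** 2).sum())
        out[name] = float(resid @ resid) / tss if tss > 0 else 0.0
    return out


def fit_lda(
    x: pd.DataFrame,
    labels: np.ndarray,
    pool_id: int | None = None,
    config: SelectionConfig | None = None,
) -> DiscriminantModel:
    """Pooled-covariance two-class LDA with equal priors.

    Coefficients a = S_pooled^{-1} (mu_+ - mu_-); the intercept places
    the decision boundary df = 0 at the midpoint of the projected class
    means, so substrates tend to positive df and nonsubstrates to
    negative df.
    """
    labels = np.asarray(labels)
    arr = x.to_numpy(dtype=np.float64)
    pos, neg = arr[labels == SUBSTRATE], arr[labels == NONSUBSTRATE]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 compounds per class")
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    sp = (np.cov(pos, rowvar=False) * (len(pos) - 1)
          + np.cov(neg, rowvar=False) * (len(neg) - 1)) / (len(pos) + len(neg) - 2)
    sp = np.atleast_2d(sp)
    try:
        coef = np.linalg.solve(sp, mu_p - mu_n)
    except np.linalg.LinAlgError:
        corr = np.corrcoef(arr, rowvar=False)
        bad = [
            x.columns[i]
            for i in range(len(x.columns))
            for j in range(i)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"singular pooled covariance; collinear descriptors: {bad}") from None
    intercept = -float(coef @ (mu_p + mu_n)) / 2.0

    f, p = _regression_fit_stats(arr, labels.astype(np.float64))
    return DiscriminantModel(
        descriptors=list(x.columns),
        coefficients=coef,
        intercept=intercept,
        pool_id=pool_id,
        f_statistic=f,
        p_value=p,
        tolerances=_tolerances(arr, list(x.columns)),
        config=config,
        n_train=len(labels),
    )


def build_model(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    pool: DescriptorPool | Sequence[str],
    config: SelectionConfig | None = None,
) -> DiscriminantModel | None:
    """Stepwise selection within a pool followed by the LDA fit.

    Returns None when selection retains no descriptor.
    """
    config = config or SelectionConfig()
    names = list(pool.descriptor_names) if isinstance(pool, DescriptorPool) else list(pool)
    x = matrix.values[names]
    chosen = stepwise_select(x, labels, config)
    if not chosen:
        return None
    model = fit_lda(
        x[chosen], labels,
        pool_id=pool.pool_id if isinstance(pool, DescriptorPool) else None,
        config=config,
    )
    return model
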