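"""Synthetic block-structured descriptor data with polyspecific labels.

Emulates the statistical shape of a curated transporter-substrate
dataset: a dense descriptor matrix organized into correlated blocks,
with the substrate/nonsubstrate label generated by *two* latent linear
"binding-site" rules joined by OR (a transporter with at least two
binding sites recognizes a compound if it fits either site), plus
label-flip noise for assay and curation error.  A single linear
discriminant cannot express the OR of two half-spaces, which is what
makes 2-model ensembles genuinely better than individual models on
these data.

Each site's rule is a deterministic linear threshold on the
descriptors, so the stored ground truth (weight vectors + thresholds)
recomputes the noiseless labels exactly.  The rule concentrates weight
``effect_size`` on a small named set of *informative* descriptors and
spreads a weak residual weight over a diffuse background set — the
site recognizes a few dominant structural features plus a faint
contribution of general physicochemistry — so ``effect_size`` directly
controls how recoverable the informative descriptors are by stepwise
selection.

Also generates decoy pools of *putative* substrates (rows sampled from
the substrate-generating region) to build screening libraries in which
the known nonsubstrates are a small minority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NONSUBSTRATE, SUBSTRATE, CompoundRecord, DescriptorMatrix

_BACKGROUND_WEIGHT = 0.3  # total diffuse-background weight at effect_size 1


@dataclass
class PolyspecificGeneratorConfig:
    """Parameters of the two-binding-site synthetic generator."""

    n_compounds: int = 262
    n_blocks: int = 12
    descriptors_per_block: int = 72
    n_informative_site1: int = 3
    n_informative_site2: int = 3
    n_background_per_site: int = 12
    effect_size: float = 1.5
    label_noise: float = 0.05
    class_balance: float = 0.6
    within_block_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_blocks < 3:
            raise ValueError("need at least 3 blocks (two informative + background)")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.n_informative_site1 > self.descriptors_per_block or (
            self.n_informative_site2 > self.descriptors_per_block
        ):
            raise ValueError("informative descriptors must fit within one block")


@dataclass
class SiteRule:
    """One binding-site rule: fires iff weights . x > threshold.

    ``descriptor_names``/``weights`` cover the full rule (informative
    plus diffuse background); ``informative_names`` is the concentrated
    subset a feature-selection method is expected to find.
    """

    descriptor_names: list[str]
    weights: np.ndarray
    threshold: float
    informative_names: list[str]

    def scores(self, matrix: DescriptorMatrix) -> np.ndarray:
        x = matrix.values[self.descriptor_names].to_numpy()
        return x @ self.weights

    def fires(self, matrix: DescriptorMatrix) -> np.ndarray:
        return self.scores(matrix) > self.threshold


@dataclass
class SyntheticDataset:
    records: list[CompoundRecord]
    matrix: DescriptorMatrix
    site1: SiteRule
    site2: SiteRule
    config: PolyspecificGeneratorConfig
    flipped_ids: list[str] = field(default_factory=list)

    def noiseless_labels(self) -> np.ndarray:
        """Recompute labels from the ground-truth rules (no flip noise)."""
        fires = self.site1.fires(self.matrix) | self.site2.fires(self.matrix)
        return np.where(fires, SUBSTRATE, NONSUBSTRATE)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def informative_names(self) -> set[str]:
        return set(self.site1.informative_names) | set(self.site2.informative_names)


def _descriptor_names(cfg: PolyspecificGeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    block_names = [f"block{k:02d}" for k in range(cfg.n_blocks)]
    d = cfg.descriptors_per_block
    names = [f"{bn}_d{j:03d}" for bn in block_names for j in range(d)]
    blocks = {bn: names[k * d : (k + 1) * d] for k, bn in enumerate(block_names)}
    return names, blocks


def _informative_cols(cfg: PolyspecificGeneratorConfig) -> tuple[list[int], list[int]]:
    d = cfg.descriptors_per_block
    return (
        list(range(0, cfg.n_informative_site1)),
        list(range(d, d + cfg.n_informative_site2)),
    )


def _draw_descriptors(rng: np.random.Generator, cfg: PolyspecificGeneratorConfig, n: int) -> np.ndarray:
    """Block-equicorrelated Gaussians; informative columns independent.

    Non-informative descriptors within a block share a common factor
    (correlation ``within_block_correlation``); the informative
    descriptors carry their own independent signal rather than the
    block's shared factor, mirroring specific recognition features
    standing out from a family of related indices.
    """
    d, rho = cfg.descriptors_per_block, cfg.within_block_correlation
    cols = []
    for _ in range(cfg.n_blocks):
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, d))
        cols.append(np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
    x = np.hstack(cols)
    for site_cols in _informative_cols(cfg):
        x[:, site_cols] = rng.standard_normal((n, len(site_cols)))
    return x


def generate_polyspecific(config: PolyspecificGeneratorConfig) -> SyntheticDataset:
    """Generate a descriptor matrix with OR-of-two-rules labels.

    The two informative sets are disjoint and live in two different
    blocks; each site's diffuse background is drawn from the remaining
    blocks.  Each rule's threshold is set from the empirical quantile
    of its score so that each rule fires with rate
    ``p = 1 - sqrt(1 - class_balance)``; the two rules are independent,
    so the OR realizes the target substrate fraction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_compounds, cfg.descriptors_per_block
    names, blocks = _descriptor_names(cfg)
    inf1, inf2 = _informative_cols(cfg)

    x = _draw_descriptors(rng, cfg, n)

    # diffuse background sets: sampled from blocks 2.. without overlap
    used = set(inf1) | set(inf2)
    backgrounds: list[list[int]] = []
    pool = [c for c in range(2 * d, cfg.n_blocks * d)]
    for remaining in (2, 1):
        avail = [c for c in pool if c not in used]
        size = min(cfg.n_background_per_site, len(avail) // remaining)
        bg = sorted(rng.choice(avail, size=size, replace=False))
        used |= set(bg)
        backgrounds.append([int(c) for c in bg])

    p_fire = 1 - np.sqrt(1 - cfg.class_balance)
    rules: list[SiteRule] = []
    fires = np.zeros(n, dtype=bool)
    for inf_cols, bg_cols in zip((inf1, inf2), backgrounds):
        w_inf = np.full(len(inf_cols), cfg.effect_size / np.sqrt(len(inf_cols)))
        w_bg = (
            np.full(len(bg_cols),
                    _BACKGROUND_WEIGHT / cfg.effect_size / np.sqrt(len(bg_cols)))
            if bg_cols else np.empty(0)
        )
        cols = list(inf_cols) + list(bg_cols)
        weights = np.concatenate([w_inf, w_bg])
        score = x[:, cols] @ weights
        thr = float(np.quantile(score, 1 - p_fire))
        rules.append(
            SiteRule(
                descriptor_names=[names[c] for c in cols],
                weights=weights,
                threshold=thr,
                informative_names=[names[c] for c in inf_cols],
            )
        )
        fires |= score > thr
    site1, site2 = rules

    if fires.all() or not fires.any():
        raise ValueError(
            "class_balance unreachable under the generated rules; "
            "adjust class_balance or rule thresholds"
        )
    labels = np.where(fires, SUBSTRATE, NONSUBSTRATE)

    flip = rng.random(n) < cfg.label_noise
    labels = np.where(flip, -labels, labels)
    ids = [f"cmpd{i:04d}" for i in range(n)]
    flipped_ids = [ids[i] for i in np.flatnonzero(flip)]

    values = pd.DataFrame(x, index=ids, columns=names)
    matrix = DescriptorMatrix(values, blocks)
    records = [CompoundRecord(id=i, label=int(l)) for i, l in zip(ids, labels)]
    return SyntheticDataset(records, matrix, site1, site2, cfg, flipped_ids)


def generate_decoys(
    dataset: SyntheticDataset, n_decoys: int, seed: int
) -> tuple[list[CompoundRecord], DescriptorMatrix]:
    """Sample putative substrates from the substrate-generating region.

    Decoys are drawn from the same generative process and accepted only
    when one of the ground-truth site rules fires, i.e. they look like
    substrates; they are flagged ``provenance="putative"`` with label
    +1, mirroring a decoy pool of compounds presumed (but not proven)
    to be transported.
    """
    if n_decoys <= 0:
        raise ValueError("n_decoys must be positive")
    cfg = dataset.config
    rng = np.random.default_rng(seed)
    names = dataset.matrix.descriptor_names
    name_idx = {nm: i for i, nm in enumerate(names)}

    def rule_fires(x: np.ndarray, rule: SiteRule) -> np.ndarray:
        cols = [name_idx[nm] for nm in rule.descriptor_names]
        return x[:, cols] @ rule.weights > rule.threshold

    accepted: list[np.ndarray] = []
    n_have = 0
    while n_have < n_decoys:
        batch = max(64, 2 * (n_decoys - n_have))
        x = _draw_descriptors(rng, cfg, batch)
        keep = rule_fires(x, dataset.site1) | rule_fires(x, dataset.site2)
        accepted.append(x[keep])
        n_have += int(keep.sum())
    x = np.vstack(accepted)[:n_decoys]

    ids = [f"decoy{i:04d}" for i in range(n_decoys)]
    values = pd.DataFrame(x, index=ids, columns=names)
    matrix = DescriptorMatrix(values, dataset.matrix.blocks)
    records = [
        CompoundRecord(id=i, label=SUBSTRATE, set="decoy", provenance="putative") for i in ids
    ]
    return records, matrix


def screening_library(
    dataset: SyntheticDataset, n_decoys: int, seed: int
) -> tuple[list[CompoundRecord], DescriptorMatrix]:
    """Test-set compounds dispersed among decoys: the simulated database."""
    test_ids = [r.id for r in dataset.records if r.set == "test"]
    if not test_ids:
        raise ValueError("dataset has no test-set compounds; assign a split first")
    test_records = [r for r in dataset.records if r.set == "test"]
    if n_decoys == 0:
        return test_records, dataset.matrix.subset_compounds(test_ids)
    decoy_records, decoy_matrix = generate_decoys(dataset, n_decoys, seed)
    values = pd.concat(
        [dataset.matrix.values.loc[test_ids], decoy_matrix.values], axis=0
    )
    return test_records + decoy_records, DescriptorMatrix(values, dataset.matrix.blocks)
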