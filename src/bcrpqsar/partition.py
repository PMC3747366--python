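"""Rational train/test splitting by two-step clustering.

Compounds are clustered *within each class* (substrates and
nonsubstrates separately), first hierarchically by structural
similarity, then refined by a k-means pass on nine normalized
structure-representation properties; finally, a class-specific
fraction of each cluster (about 50% of each substrate cluster, 25% of
each nonsubstrate cluster) is drawn into the external test set, so the
test set samples every structural family while the training set stays
balanced.

The structural stage uses complete-linkage agglomerative clustering on
1 - Tanimoto similarity of topological path fingerprints — an open,
exactly reproducible stand-in for approximate maximum-common-
substructure library clustering, with the MCS-size floor mapped to a
similarity cutoff.  When compounds carry no SMILES (synthetic,
descriptor-space data) the same hierarchy is built on Euclidean
distances over the normalized property descriptors instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io import NONSUBSTRATE, SUBSTRATE, CompoundRecord, DescriptorMatrix

logger = logging.getLogger(__name__)


@dataclass
class PartitionConfig:
    property_descriptors: tuple[str, ...] = ()
    similarity_cutoff: float = 0.35   # Tanimoto floor standing in for a 9-atom MCS
    min_common_substructure_atoms: int = 9
    test_fraction_substrates: float = 0.50
    test_fraction_nonsubstrates: float = 0.25
    k_per_class: dict[int, int] | None = None  # default: hierarchical cluster count
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.test_fraction_substrates, self.test_fraction_nonsubstrates):
            if not 0 < frac < 1:
                raise ValueError("test fractions must lie in (0, 1)")
        if self.min_common_substructure_atoms < 1:
            raise ValueError("min_common_substructure_atoms must be >= 1")

    def test_fraction(self, label: int) -> float:
        return (
            self.test_fraction_substrates if label == SUBSTRATE
            else self.test_fraction_nonsubstrates
        )


# ----------------------------------------------------------------------
# Stage 1: hierarchical clustering within each class
# ----------------------------------------------------------------------

def _fingerprint_distance(smiles: Sequence[str]) -> np.ndarray:
    from rdkit import Chem, DataStructs

    mols = [Chem.MolFromSmiles(s) for s in smiles]
    bad = [s for s, m in zip(smiles, mols) if m is None]
    if bad:
        raise ValueError(f"invalid SMILES: {bad}")
    fps = [Chem.RDKFingerprint(m) for m in mols]
    n = len(fps)
    dist = np.zeros((n, n))
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        dist[i, i + 1:] = dist[i + 1:, i] = 1 - np.asarray(sims)
    return dist


def hierarchical_structural_clusters(
    records: Sequence[CompoundRecord],
    config: PartitionConfig,
    matrix: DescriptorMatrix | None = None,
) -> dict[str, int]:
    """Initial cluster labels per compound, clustered within each class.

    Uses complete linkage cut at distance 1 - similarity_cutoff.  For
    records without SMILES, ``matrix`` (restricted to the configured
    property descriptors, z-scored) supplies the distances instead.
    Cluster ids are globally unique across the two classes.
    """
    labels: dict[str, int] = {}
    next_id = 0
    for cls in (SUBSTRATE, NONSUBSTRATE):
        members = [r for r in records if r.label == cls]
        if not members:
            continue
        if len(members) < 2:
            warnings.warn(
                f"class {cls:+d} has fewer than 2 compounds: single cluster", stacklevel=2
            )
            labels[members[0].id] = next_id
            next_id += 1
            continue
        if all(r.smiles for r in members):
            dist = _fingerprint_distance([r.smiles for r in members])
            cut = 1 - config.similarity_cutoff
        else:
            if matrix is None:
                raise ValueError("records lack SMILES; a descriptor matrix is required")
            names = list(config.property_descriptors) or matrix.descriptor_names[:9]
            sub = matrix.values.loc[[r.id for r in members], names]
            z = (sub - sub.mean()) / sub.std(ddof=0).replace(0, 1)
            dist = squareform(pdist(z.to_numpy()))
            # cut at the median pairwise distance: a scale-free default
            cut = float(np.median(dist[np.triu_indices(len(members), 1)]))
        z_link = linkage(squareform(dist, checks=False), method="complete")
        assignments = fcluster(z_link, t=cut, criterion="distance")
        for rec, a in zip(members, assignments):
            labels[rec.id] = next_id + int(a) - 1
        next_id += int(assignments.max())
    return labels


# ----------------------------------------------------------------------
# Stage 2: k-means refinement on normalized property descriptors
# ----------------------------------------------------------------------

def _kmeans_objective(x: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = x[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def kmeans_refine(
    initial_labels: np.ndarray,
    x: np.ndarray,
    max_iter: int = 200,
) -> np.ndarray:
    """Refine cluster labels by single-point improvement (Hartigan-style).

    Starting from the hierarchical labels, repeatedly move the single
    point whose reassignment most decreases the total within-cluster
    squared Euclidean distance, until no move helps.  On convergence no
    single-point reassignment can decrease the objective; empty
    clusters are never created (a cluster's last member stays put).
    Deterministic: points and clusters are scanned in index order.
    """
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(initial_labels).copy()
    uniq = np.unique(labels)
    if len(uniq) > len(x):
        raise ValueError("more clusters than points")
    remap = {c: i for i, c in enumerate(uniq)}
    labels = np.array([remap[c] for c in labels])
    k = len(uniq)
    if k == 1:
        return labels

    centers = np.vstack([x[labels == c].mean(axis=0) for c in range(k)])
    sizes = np.bincount(labels, minlength=k).astype(float)

    for _ in range(max_iter * len(x)):
        best_gain, best_move = -1e-12, None
        for i in range(len(x)):
            a = labels[i]
            if sizes[a] <= 1:
                continue
            d_a = float(((x[i] - centers[a]) ** 2).sum())
            remove_gain = sizes[a] / (sizes[a] - 1) * d_a
            for b in range(k):
                if b == a:
                    continue
                d_b = float(((x[i] - centers[b]) ** 2).sum())
                add_cost = sizes[b] / (sizes[b] + 1) * d_b
                gain = remove_gain - add_cost
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, (i, b)
        if best_move is None:
            break
        i, b = best_move
        a = labels[i]
        centers[a] = (centers[a] * sizes[a] - x[i]) / (sizes[a] - 1)
        centers[b] = (centers[b] * sizes[b] + x[i]) / (sizes[b] + 1)
        sizes[a] -= 1
        sizes[b] += 1
        labels[i] = b
    return labels


def refine_clusters(
    records: Sequence[CompoundRecord],
    initial: dict[str, int],
    matrix: DescriptorMatrix,
    config: PartitionConfig,
) -> dict[str, int]:
    """Run the k-means refinement class-by-class on z-scored properties."""
    names = list(config.property_descriptors) or matrix.descriptor_names[:9]
    refined: dict[str, int] = {}
    next_id = 0
    for cls in (SUBSTRATE, NONSUBSTRATE):
        members = [r for r in records if r.label == cls]
        if not members:
            continue
        ids = [r.id for r in members]
        sub = matrix.values.loc[ids, names]
        z = ((sub - sub.mean()) / sub.std(ddof=0).replace(0, 1)).to_numpy()
        init = np.array([initial[i] for i in ids])
        new = kmeans_refine(init, z)
        for i, c in zip(ids, new):
            refined[i] = next_id + int(c)
        next_id += int(new.max()) + 1
    return refined


# ----------------------------------------------------------------------
# Stage 3: cluster-wise class-stratified assignment
# ----------------------------------------------------------------------

@dataclass
class SplitPlan:
    assignments: dict[str, str]           # id -> "train" | "test"
    clusters: dict[str, int]              # id -> cluster
    per_cluster: pd.DataFrame = field(repr=False, default=None)

    @property
    def train_ids(self) -> list[str]:
        return [i for i, s in self.assignments.items() if s == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [i for i, s in self.assignments.items() if s == "test"]

    def to_csv(self, path, records: Sequence[CompoundRecord]) -> None:
        rows = [
            {
                "id": r.id, "class": r.label,
                "cluster": self.clusters[r.id], "set": self.assignments[r.id],
            }
            for r in records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def _round_half_even(value: float) -> int:
    return int(np.round(value))  # numpy rounds half to even


def assign_split(
    clusters: dict[str, int],
    records: Sequence[CompoundRecord],
    config: PartitionConfig,
) -> SplitPlan:
    """Draw the configured test fraction from each cluster of each class.

    Per cluster, round-half-to-even of fraction*size compounds go to
    the test set by a seeded draw; singleton clusters go entirely to
    train, keeping rare scaffolds available for model fitting.
    """
    rng = np.random.default_rng(config.seed)
    assignments: dict[str, str] = {}
    table = []
    for cls in (SUBSTRATE, NONSUBSTRATE):
        frac = config.test_fraction(cls)
        members = [r for r in records if r.label == cls]
        by_cluster: dict[int, list[str]] = {}
        for r in members:
            by_cluster.setdefault(clusters[r.id], []).append(r.id)
        for cid in sorted(by_cluster):
            ids = sorted(by_cluster[cid])
            if len(ids) == 1:
                n_test = 0
            else:
                n_test = _round_half_even(frac * len(ids))
            test_ids = set(rng.choice(ids, size=n_test, replace=False)) if n_test else set()
            for i in ids:
                assignments[i] = "test" if i in test_ids else "train"
            table.append({
                "class": cls, "cluster": cid, "size": len(ids),
                "n_test": n_test, "n_train": len(ids) - n_test,
            })
    for r in records:
        r.set = assignments[r.id]
        r.cluster = clusters[r.id]
    return SplitPlan(assignments=assignments, clusters=dict(clusters),
                     per_cluster=pd.DataFrame(table))


def rational_split(
    records: Sequence[CompoundRecord],
    matrix: DescriptorMatrix,
    config: PartitionConfig | None = None,
) -> SplitPlan:
    """Full two-step clustering partition: hierarchy, k-means, assignment."""
    config = config or PartitionConfig()
    initial = hierarchical_structural_clusters(records, config, matrix=matrix)
    refined = refine_clusters(records, initial, matrix, config)
    return assign_split(refined, records, config)
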