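"""Model quality protocols.

Confusion-matrix summaries (with an explicit positive-class
orientation: in a screening campaign looking for compounds NOT
transported, the positives are the nonsubstrates), a label-scrambling
randomization test, stratified leave-group-out cross-validation with
coverage checking, and external test-set evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import NONSUBSTRATE, SUBSTRATE, DescriptorMatrix
from .subspace import DiscriminantModel, SelectionConfig, build_model

logger = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    """TP/FP/TN/FN counts with Se = TP/(TP+FN), Sp = TN/(TN+FP)."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "nonsubstrate"

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Se": self.sensitivity, "Sp": self.specificity,
            "accuracy": self.accuracy, "positive_class": self.positive_class,
        }


def confusion(
    calls: Sequence[int] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    positive_class: str = "nonsubstrate",
) -> ConfusionSummary:
    """Count the confusion matrix of +/-1 calls against +/-1 labels.

    ``positive_class`` names which class counts as a positive; the
    orientation is recorded in the summary so Se and Sp are
    unambiguous.
    """
    calls = np.asarray(calls)
    labels = np.asarray(labels)
    if len(calls) == 0:
        raise ValueError("empty input")
    if len(calls) != len(labels):
        raise ValueError("calls and labels must be aligned")
    pos = NONSUBSTRATE if positive_class == "nonsubstrate" else SUBSTRATE
    call_pos, label_pos = calls == pos, labels == pos
    return ConfusionSummary(
        tp=int((call_pos & label_pos).sum()),
        fp=int((call_pos & ~label_pos).sum()),
        tn=int((~call_pos & ~label_pos).sum()),
        fn=int((~call_pos & label_pos).sum()),
        positive_class=positive_class,
    )


def model_confusion(
    model: DiscriminantModel,
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    positive_class: str = "nonsubstrate",
    threshold: float = 0.0,
) -> ConfusionSummary:
    return confusion(model.classify(matrix, threshold), labels, positive_class)


# ----------------------------------------------------------------------
# Randomization (y-scrambling) test
# ----------------------------------------------------------------------

@dataclass
class RandomizationResult:
    accuracies: np.ndarray
    not_run: bool = False

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean()) if len(self.accuracies) else np.nan

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else np.nan


def randomization_test(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    pool: Sequence[str],
    config: SelectionConfig | None = None,
    n_random: int = 50,
    seed: int = 0,
) -> RandomizationResult:
    """Scramble labels, rebuild stepwise+LDA, record training accuracy.

    Descriptor selection is redone on every scramble (the stronger
    null).  A scramble on which selection retains nothing contributes
    the majority-class rate.
    """
    if n_random == 0:
        logger.info("randomization test not run (n_random=0)")
        return RandomizationResult(np.array([]), not_run=True)
    config = config or SelectionConfig()
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    majority = max(np.mean(labels == SUBSTRATE), np.mean(labels == NONSUBSTRATE))
    accs = np.empty(n_random)
    for r in range(n_random):
        scrambled = rng.permutation(labels)
        model = build_model(matrix, scrambled, pool, config)
        if model is None:
            logger.info("randomization rep %d: no descriptor selected", r)
            accs[r] = majority
        else:
            accs[r] = confusion(model.classify(matrix), scrambled).accuracy
    return RandomizationResult(accs)


# ----------------------------------------------------------------------
# Stratified leave-group-out cross-validation
# ----------------------------------------------------------------------

@dataclass
class LGOResult:
    accuracies: np.ndarray
    coverage: bool

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else np.nan


def _stratified_group(
    rng: np.random.Generator,
    unseen: set[int],
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
    group_size: int,
) -> list[int]:
    """Draw one removal group preserving the class ratio within +/-1.

    Compounds not yet left out are drawn first, so that coverage of the
    whole training set is achieved by construction once enough rounds
    have run.
    """
    n = len(pos_idx) + len(neg_idx)
    n_pos = int(round(group_size * len(pos_idx) / n))
    n_pos = min(max(n_pos, 0), group_size)
    picks: list[int] = []
    for idx, k in ((pos_idx, n_pos), (neg_idx, group_size - n_pos)):
        fresh = np.array(sorted(set(idx) & unseen), dtype=int)
        stale = np.array(sorted(set(idx) - unseen), dtype=int)
        take_fresh = min(k, len(fresh))
        if take_fresh:
            picks.extend(rng.choice(fresh, size=take_fresh, replace=False))
        if k - take_fresh:
            picks.extend(rng.choice(stale, size=k - take_fresh, replace=False))
    return picks


def lgo_cv(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    pool: Sequence[str],
    config: SelectionConfig | None = None,
    group_size: int = 10,
    rounds: int = 50,
    seed: int = 0,
) -> LGOResult:
    """Leave-group-out CV: remove a stratified group, rebuild, predict it.

    The sampler prioritizes compounds not yet removed, so after enough
    rounds every training compound has been left out at least once; the
    report carries a coverage flag asserting exactly that.
    """
    config = config or SelectionConfig()
    labels = np.asarray(labels)
    n = len(labels)
    if group_size >= n:
        raise ValueError("group_size must be smaller than the training set")
    pos_idx = np.flatnonzero(labels == SUBSTRATE)
    neg_idx = np.flatnonzero(labels == NONSUBSTRATE)
    rng = np.random.default_rng(seed)
    unseen = set(range(n))
    ids = matrix.compound_ids
    accs = np.empty(rounds)
    for r in range(rounds):
        group = _stratified_group(rng, unseen, pos_idx, neg_idx, group_size)
        unseen -= set(group)
        keep = sorted(set(range(n)) - set(group))
        train_mat = matrix.subset_compounds([ids[i] for i in keep])
        model = build_model(train_mat, labels[keep], pool, config)
        held = matrix.subset_compounds([ids[i] for i in group])
        if model is None:
            majority = SUBSTRATE if len(pos_idx) >= len(neg_idx) else NONSUBSTRATE
            calls = np.full(len(group), majority)
        else:
            calls = model.classify(held)
        accs[r] = confusion(calls, labels[group]).accuracy
    coverage = not unseen
    if not coverage:
        logger.warning("LGO coverage incomplete: %d compounds never removed", len(unseen))
    return LGOResult(accs, coverage)


@dataclass
class ValidationReport:
    randomization: RandomizationResult
    lgo: LGOResult
    external: ConfusionSummary
    training: ConfusionSummary

    def as_dict(self) -> dict:
        return {
            "randomization": {
                "mean": self.randomization.mean, "sd": self.randomization.sd,
                "n": len(self.randomization.accuracies),
                "not_run": self.randomization.not_run,
            },
            "lgo": {
                "mean": self.lgo.mean, "sd": self.lgo.sd,
                "rounds": len(self.lgo.accuracies), "coverage": self.lgo.coverage,
            },
            "external": self.external.as_dict(),
            "training": self.training.as_dict(),
        }

    def text_table(self) -> str:
        """Human-readable block mirroring a per-model results table."""
        e, t = self.external, self.training
        lines = [
            f"training:  Sp {t.specificity:.1%}  Se {t.sensitivity:.1%}  acc {t.accuracy:.1%}"
            f"  (positive class: {t.positive_class})",
            f"test:      Sp {e.specificity:.1%}  Se {e.sensitivity:.1%}  acc {e.accuracy:.1%}",
            f"LGO CV:    {self.lgo.mean:.1%} (+/-{self.lgo.sd:.1%})"
            f"  coverage={'yes' if self.lgo.coverage else 'NO'}",
        ]
        if self.randomization.not_run:
            lines.append("randomization: not run")
        else:
            lines.append(
                f"randomization: {self.randomization.mean:.1%} (+/-{self.randomization.sd:.1%})"
            )
        return "\n".join(lines)


def validate_model(
    model: DiscriminantModel,
    train_matrix: DescriptorMatrix,
    train_labels: np.ndarray,
    test_matrix: DescriptorMatrix,
    test_labels: np.ndarray,
    pool: Sequence[str],
    config: SelectionConfig | None = None,
    n_random: int = 50,
    lgo_rounds: int = 50,
    lgo_group_size: int = 10,
    seed: int = 0,
) -> ValidationReport:
    """Full protocol: randomization + LGO + external test evaluation."""
    return ValidationReport(
        randomization=randomization_test(
            train_matrix, train_labels, pool, config, n_random=n_random, seed=seed
        ),
        lgo=lgo_cv(
            train_matrix, train_labels, pool, config,
            group_size=lgo_group_size, rounds=lgo_rounds, seed=seed + 1,
        ),
        external=model_confusion(model, test_matrix, test_labels),
        training=model_confusion(model, train_matrix, train_labels),
    )
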