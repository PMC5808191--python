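"""Frequency-based feature selection over the best base classifiers.

The base classifiers are ranked by individual test accuracy; the
feature subsets of the top K form a K x f index matrix whose entry
frequencies identify "important features".  A prefix sweep over the
important-feature list (drawing each cluster's random feature subsets
from the first q entries only) locates the optimal feature set, which
is finally mapped to per-region weights.

All orderings are made deterministic by explicit tie rules: classifier
ties break by ascending classifier index, frequency ties by ascending
feature index, and accuracy ties in the q sweep by the smallest q.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ensemble import (
    EnsembleConfig,
    RandomSVMCluster,
    accuracy,
    build_cluster,
    predict,
)
from .features import FeatureIndexMap, LabeledDataset

DEFAULT_TOP_CLASSIFIERS = 100
DEFAULT_N_IMPORTANT = 400


def rank_classifiers(accuracies: Sequence[float]) -> np.ndarray:
    """Classifier indices sorted by descending accuracy, stable on ties."""
    accuracies = np.asarray(accuracies)
    if accuracies.size == 0:
        raise ValueError("no classifier accuracies to rank")
    return np.argsort(-accuracies, kind="stable")


@dataclass
class FeatureFrequencyTable:
    """Occurrence counts of feature indices in the top-K subsets."""

    counts: dict[int, int]
    source: np.ndarray  # K x f matrix of feature indices

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


def feature_frequency(
    cluster: RandomSVMCluster,
    ranked_idx: Sequence[int],
    K: int = DEFAULT_TOP_CLASSIFIERS,
) -> FeatureFrequencyTable:
    """Count feature occurrences across the K best classifiers' subsets."""
    if K > cluster.n_classifiers:
        raise ValueError(
            f"K={K} exceeds the number of base classifiers {cluster.n_classifiers}"
        )
    top = np.asarray(ranked_idx)[:K]
    source = np.array([cluster.classifiers[i].feature_indices for i in top])
    values, counts = np.unique(source, return_counts=True)
    return FeatureFrequencyTable(
        counts={int(v): int(c) for v, c in zip(values, counts)}, source=source
    )


@dataclass
class ImportantFeatures:
    """Feature indices ordered by descending frequency."""

    indices: np.ndarray
    frequencies: np.ndarray

    def __len__(self) -> int:
        return len(self.indices)


def important_features(
    table: FeatureFrequencyTable, M: int = DEFAULT_N_IMPORTANT
) -> ImportantFeatures:
    """The top-M features by frequency (ties broken by ascending index).

    If fewer than M distinct features were counted, all of them are
    returned.
    """
    if M < 1:
        raise ValueError("M must be at least 1")
    items = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:M]
    return ImportantFeatures(
        indices=np.array([k for k, _ in items], dtype=int),
        frequencies=np.array([v for _, v in items], dtype=int),
    )


def default_q_range() -> list[int]:
    """Prefix lengths 70, 72, ..., 400 of the q sweep (166 values)."""
    return list(range(70, 401, 2))


@dataclass
class OptimalFeatureSet:
    q: int
    feature_indices: np.ndarray
    accuracy: float
    curve: list[tuple[int, float]] = field(default_factory=list)


def optimal_feature_search(
    train: LabeledDataset,
    test: LabeledDataset,
    important: ImportantFeatures,
    config: EnsembleConfig,
    q_range: Sequence[int] | None = None,
) -> OptimalFeatureSet:
    """Find the important-feature prefix giving the best ensemble accuracy.

    For each q, a full random SVM cluster is built whose per-classifier
    feature subsets are drawn from the first q important features only
    (fresh seeded subsets per q).  The optimal q is the smallest one
    attaining the maximum test accuracy.
    """
    q_range = sorted(default_q_range() if q_range is None else q_range)
    if not q_range:
        raise ValueError("q_range must be nonempty")
    if q_range[0] < config.features_per_svm:
        raise ValueError(
            f"smallest q ({q_range[0]}) is below features_per_svm "
            f"({config.features_per_svm})"
        )
    if q_range[-1] > len(important):
        q_range = [q for q in q_range if q <= len(important)]
        if not q_range:
            raise ValueError("no q in range is covered by the important features")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(len(q_range))
    curve: list[tuple[int, float]] = []
    best_q, best_acc = None, -1.0
    for q, sub_seed in zip(q_range, child_seeds):
        cfg = replace(config, seed=int(sub_seed % 2**31))
        cluster = build_cluster(
            train, cfg, candidate_features=important.indices[:q]
        )
        acc = accuracy(predict(cluster, test.X), test.y)
        curve.append((q, acc))
        if acc > best_acc:
            best_q, best_acc = q, acc
    return OptimalFeatureSet(
        q=best_q,
        feature_indices=important.indices[:best_q].copy(),
        accuracy=best_acc,
        curve=curve,
    )


def region_weights(
    selected: OptimalFeatureSet | Sequence[int], fmap: FeatureIndexMap
) -> np.ndarray:
    """Count how many selected features touch each region.

    Degree, local-efficiency and clustering features credit their single
    region; shortest-path features credit both endpoint regions, so the
    weights sum to (#single-region features) + 2 * (#pair features).
    """
    indices = (
        selected.feature_indices
        if isinstance(selected, OptimalFeatureSet)
        else np.asarray(selected, dtype=int)
    )
    weights = np.zeros(fmap.n_regions, dtype=int)
    for idx in indices:
        fam, i, j = fmap.descriptor_of(int(idx))
        weights[i] += 1
        if j is not None:
            weights[j] += 1
    return weights
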