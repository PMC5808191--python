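"""Canonical feature vectors, the feature-index map, and labelled datasets.

For an N-region network each subject contributes 3N + N(N-1)/2 features
in a fixed order: the N degrees, the N(N-1)/2 upper-triangle shortest
paths in row-major pair order, the N local efficiencies, then the N
clustering coefficients.  Fixing this order is what makes ensemble
feature-frequency counting and region-weight mapping reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from sklearn.model_selection import train_test_split

from .graph import GraphMetrics
from .regions import default_region_ids

METRIC_FAMILIES = ("degree", "shortest_path", "local_efficiency", "clustering")

_FAMILY_PREFIX = {
    "degree": "DEG",
    "shortest_path": "SP",
    "local_efficiency": "EFF",
    "clustering": "CC",
}


class FeatureDescriptor(NamedTuple):
    """What one feature index means: a metric family and its region(s)."""

    family: str
    region_i: int
    region_j: int | None = None


@dataclass
class FeatureIndexMap:
    """Bijection between flat feature indices and metric/region descriptors."""

    n_regions: int
    entries: list[FeatureDescriptor]

    def __len__(self) -> int:
        return len(self.entries)

    def descriptor_of(self, index: int) -> FeatureDescriptor:
        return self.entries[index]

    def index_of(self, desc: FeatureDescriptor) -> int:
        n = self.n_regions
        fam = desc.family
        if fam == "degree":
            return desc.region_i
        if fam == "shortest_path":
            i, j = sorted((desc.region_i, desc.region_j))
            # offset of pair (i, j), i < j, in row-major upper-triangle order
            return n + (i * (2 * n - i - 1)) // 2 + (j - i - 1)
        n_pairs = n * (n - 1) // 2
        if fam == "local_efficiency":
            return n + n_pairs + desc.region_i
        if fam == "clustering":
            return 2 * n + n_pairs + desc.region_i
        raise ValueError(f"unknown metric family {fam!r}")

    def feature_names(self, region_ids: list[str] | None = None) -> list[str]:
        """Human-readable names, e.g. ``SP:PreCG.R-IFGtriang.R``."""
        ids = region_ids or default_region_ids(self.n_regions)
        names = []
        for fam, i, j in self.entries:
            prefix = _FAMILY_PREFIX[fam]
            if j is None:
                names.append(f"{prefix}:{ids[i]}")
            else:
                names.append(f"{prefix}:{ids[i]}-{ids[j]}")
        return names


def build_index_map(n_regions: int) -> FeatureIndexMap:
    """The canonical feature ordering for an ``n_regions``-node network."""
    if n_regions < 2:
        raise ValueError(f"need at least 2 regions, got {n_regions}")
    entries: list[FeatureDescriptor] = [
        FeatureDescriptor("degree", i) for i in range(n_regions)
    ]
    entries.extend(
        FeatureDescriptor("shortest_path", i, j)
        for i in range(n_regions)
        for j in range(i + 1, n_regions)
    )
    entries.extend(FeatureDescriptor("local_efficiency", i) for i in range(n_regions))
    entries.extend(FeatureDescriptor("clustering", i) for i in range(n_regions))
    return FeatureIndexMap(n_regions, entries)


def n_features(n_regions: int) -> int:
    return 3 * n_regions + n_regions * (n_regions - 1) // 2


def assemble_features(m: GraphMetrics, fmap: FeatureIndexMap) -> np.ndarray:
    """Flatten one subject's graph metrics into the canonical vector."""
    n = fmap.n_regions
    for name in ("degree", "local_efficiency", "clustering"):
        if getattr(m, name).shape != (n,):
            raise ValueError(f"{name} has shape {getattr(m, name).shape}, expected ({n},)")
    if m.shortest_path.shape != (n, n):
        raise ValueError(
            f"shortest_path has shape {m.shortest_path.shape}, expected ({n}, {n})"
        )
    iu = np.triu_indices(n, k=1)
    return np.concatenate(
        [
            np.asarray(m.degree, dtype=float),
            np.asarray(m.shortest_path, dtype=float)[iu],
            np.asarray(m.local_efficiency, dtype=float),
            np.asarray(m.clustering, dtype=float),
        ]
    )


@dataclass
class LabeledDataset:
    """Feature matrix with -1 (patient) / +1 (control) labels."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length does not match number of rows of X")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("labels must be -1 or +1")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(len(self.y))]
        if len(self.subject_ids) != len(self.y):
            raise ValueError("subject_ids length does not match y")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows)
        return LabeledDataset(
            self.X[rows], self.y[rows], [self.subject_ids[i] for i in rows]
        )


@dataclass
class SplitDataset:
    train: LabeledDataset
    test: LabeledDataset
    seed: int


def split_dataset(
    ds: LabeledDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> SplitDataset:
    """Partition subjects into train/test with |train| = floor(f * n).

    Floor rounding makes 84 subjects at a 7:3 ratio split 58/26.
    Stratification (default) keeps class proportions within one subject
    per class; disable it for a purely random partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = ds.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects to split")
    n_train = int(np.floor(train_fraction * n))
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=n_train,
        random_state=seed,
        stratify=ds.y if stratified else None,
        shuffle=True,
    )
    train = ds.subset(np.sort(train_idx))
    test = ds.subset(np.sort(test_idx))
    for part, name in ((train, "train"), (test, "test")):
        if np.unique(part.y).size < 2 and name == "train":
            raise ValueError("a class is absent from the training partition")
    return SplitDataset(train=train, test=test, seed=seed)
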