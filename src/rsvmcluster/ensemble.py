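"""The random SVM cluster: a random-subspace ensemble of RBF SVMs.

Each base classifier is a hard-margin RBF support vector machine fitted
on a random subset of training subjects (without replacement) and a
random subset of features (without replacement).  The ensemble predicts
by majority vote over its base classifiers; even-split votes are broken
by the sign of the summed real-valued decision outputs and, failing
that, assigned +1.

Defaults follow the published protocol: B = 500 base classifiers, s =
50 subjects and f = 62 features per classifier, RBF width sigma = 3,
and an effectively infinite margin penalty (1e10).

Two conventions are offered for the kernel distance.  The default
("rms") measures the root-mean-square feature difference, K(x, z) =
exp(-mean_f (x_f - z_f)^2 / (2 sigma^2)), so a width of 3 means "3
standardized units per feature" regardless of how many features a base
classifier drew.  The plain summed Euclidean convention ("euclidean",
K = exp(-||x-z||^2 / (2 sigma^2)), gamma = 1/18 at sigma = 3) is kept
as an option; note that over f = 62 standardized features typical
squared distances are ~2f, which drives all off-diagonal kernel values
toward zero and degrades every hard-margin base SVM to a near-constant
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .features import LabeledDataset

_MAX_REDRAWS = 100


@dataclass
class EnsembleConfig:
    """Hyper-parameters of the random SVM cluster."""

    n_classifiers: int = 500
    samples_per_svm: int = 50
    features_per_svm: int = 62
    rbf_width: float = 3.0
    penalty: float = 1e10
    standardize: bool = True
    kernel_distance: str = "rms"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classifiers", "samples_per_svm", "features_per_svm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.rbf_width <= 0:
            raise ValueError("rbf_width must be positive")
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.kernel_distance not in ("rms", "euclidean"):
            raise ValueError("kernel_distance must be 'rms' or 'euclidean'")

    def gamma(self, n_subspace_features: int) -> float:
        """scikit-learn's gamma for the sigma-parameterized RBF kernel."""
        g = 1.0 / (2.0 * self.rbf_width**2)
        if self.kernel_distance == "rms":
            g /= n_subspace_features
        return g


@dataclass
class BaseSVM:
    """One fitted base classifier and the index subsets that defined it."""

    sample_indices: np.ndarray
    feature_indices: np.ndarray
    model: SVC

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X[:, self.feature_indices]).astype(int)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(X[:, self.feature_indices])


@dataclass
class RandomSVMCluster:
    """B base SVMs plus the training-set standardization parameters."""

    classifiers: list[BaseSVM]
    config: EnsembleConfig
    center: np.ndarray
    scale: np.ndarray

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    @property
    def n_features(self) -> int:
        return self.center.shape[0]

    def standardized(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"X has {X.shape[1]} features, cluster was trained on {self.n_features}"
            )
        return (X - self.center) / self.scale


def train_base_svm(
    train: LabeledDataset,
    sample_idx: Sequence[int],
    feature_idx: Sequence[int],
    config: EnsembleConfig,
    X_std: np.ndarray | None = None,
) -> BaseSVM:
    """Fit one RBF SVM on the given subject and feature subsets.

    ``X_std`` may carry a pre-standardized copy of ``train.X`` so the
    cluster builder does not rescale once per classifier.
    """
    sample_idx = np.asarray(sample_idx)
    feature_idx = np.asarray(feature_idx)
    y_sub = train.y[sample_idx]
    if np.unique(y_sub).size < 2:
        raise ValueError("sampled subject subset contains a single class")
    X = X_std if X_std is not None else train.X
    X_sub = X[np.ix_(sample_idx, feature_idx)]
    model = SVC(kernel="rbf", gamma=config.gamma(feature_idx.size), C=config.penalty)
    model.fit(X_sub, y_sub)
    return BaseSVM(sample_indices=sample_idx, feature_indices=feature_idx, model=model)


def _standardization(train: LabeledDataset, config: EnsembleConfig):
    if config.standardize:
        center = train.X.mean(axis=0)
        scale = train.X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        center = np.zeros(train.X.shape[1])
        scale = np.ones(train.X.shape[1])
    return center, scale


def build_cluster(
    train: LabeledDataset,
    config: EnsembleConfig,
    candidate_features: Sequence[int] | None = None,
) -> RandomSVMCluster:
    """Train the B base classifiers of a random SVM cluster.

    Subject and feature subsets are drawn without replacement from a
    generator seeded by ``config.seed``, so identical configurations
    reproduce identical clusters.  Subject draws containing a single
    class are rejected and redrawn.  ``candidate_features`` restricts
    the feature pool (used by the optimal-feature-set search); by
    default all columns of ``train.X`` are candidates.
    """
    if np.unique(train.y).size < 2:
        raise ValueError("training set must contain both classes")
    pool = (
        np.arange(train.n_features)
        if candidate_features is None
        else np.asarray(candidate_features)
    )
    if config.samples_per_svm > train.n_subjects:
        raise ValueError(
            f"samples_per_svm={config.samples_per_svm} exceeds training size "
            f"{train.n_subjects}"
        )
    if config.features_per_svm > pool.size:
        raise ValueError(
            f"features_per_svm={config.features_per_svm} exceeds feature pool "
            f"size {pool.size}"
        )
    rng = np.random.default_rng(config.seed)
    center, scale = _standardization(train, config)
    X_std = (train.X - center) / scale
    classifiers: list[BaseSVM] = []
    for _ in range(config.n_classifiers):
        for attempt in range(_MAX_REDRAWS):
            sample_idx = rng.choice(
                train.n_subjects, size=config.samples_per_svm, replace=False
            )
            if np.unique(train.y[sample_idx]).size == 2:
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class subject subset in {_MAX_REDRAWS} attempts"
            )
        feature_idx = rng.choice(pool, size=config.features_per_svm, replace=False)
        classifiers.append(
            train_base_svm(train, sample_idx, feature_idx, config, X_std=X_std)
        )
    return RandomSVMCluster(
        classifiers=classifiers, config=config, center=center, scale=scale
    )


def base_votes(cluster: RandomSVMCluster, X: np.ndarray) -> np.ndarray:
    """B x n matrix of per-classifier predicted labels (each in {-1, +1})."""
    X_std = cluster.standardized(np.asarray(X, dtype=float))
    return np.array([clf.predict(X_std) for clf in cluster.classifiers])


def predict(cluster: RandomSVMCluster, X: np.ndarray) -> np.ndarray:
    """Majority-vote ensemble prediction for each row of ``X``."""
    X = np.asarray(X, dtype=float)
    votes = base_votes(cluster, X)
    tally = votes.sum(axis=0)  # (+1 votes) - (-1 votes)
    pred = np.sign(tally)
    ties = np.flatnonzero(pred == 0)
    if ties.size:
        X_std = cluster.standardized(X[ties])
        dec = np.zeros(ties.size)
        for clf in cluster.classifiers:
            dec += clf.decision_values(X_std)
        pred[ties] = np.where(dec >= 0, 1, -1)
    return pred.astype(int)


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of exact label matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label vectors differ in length")
    return float(np.mean(predicted == truth))


def evaluate_base_classifiers(
    cluster: RandomSVMCluster, test: LabeledDataset
) -> np.ndarray:
    """Individual test accuracy of each base classifier (length B)."""
    votes = base_votes(cluster, test.X)
    return (votes == test.y).mean(axis=1)


def default_size_range() -> list[int]:
    """Ensemble sizes 5, 10, ..., 700 of the size sweep (140 values)."""
    return list(range(5, 701, 5))


@dataclass
class SweepResult:
    sizes: list[int]
    accuracies: list[float]
    optimal_size: int = field(init=False)

    def __post_init__(self) -> None:
        best = max(self.accuracies)
        self.optimal_size = self.sizes[self.accuracies.index(best)]


def ensemble_size_sweep(
    train: LabeledDataset,
    test: LabeledDataset,
    config: EnsembleConfig,
    sizes: Sequence[int] | None = None,
    mode: str = "fresh",
) -> SweepResult:
    """Ensemble accuracy as a function of the number of base classifiers.

    ``mode='fresh'`` builds an independent cluster per size (each with a
    sub-seed derived from ``config.seed``); ``mode='prefix'`` builds one
    cluster at the largest size and evaluates its prefixes, which is
    cheaper but makes the curves nested rather than independent.  The
    optimal size is the smallest one attaining the maximum accuracy.
    """
    sizes = list(default_size_range() if sizes is None else sizes)
    if not sizes:
        raise ValueError("sizes must be nonempty")
    accs: list[float] = []
    if mode == "fresh":
        child_seeds = np.random.SeedSequence(config.seed).generate_state(len(sizes))
        for size, sub_seed in zip(sizes, child_seeds):
            cfg = replace(config, n_classifiers=size, seed=int(sub_seed % 2**31))
            cluster = build_cluster(train, cfg)
            accs.append(accuracy(predict(cluster, test.X), test.y))
    elif mode == "prefix":
        cfg = replace(config, n_classifiers=max(sizes))
        full = build_cluster(train, cfg)
        votes = base_votes(full, test.X)
        dec = np.array(
            [clf.decision_values(full.standardized(test.X)) for clf in full.classifiers]
        )
        for size in sizes:
            tally = votes[:size].sum(axis=0)
            pred = np.sign(tally)
            tie = pred == 0
            pred[tie] = np.where(dec[:size].sum(axis=0)[tie] >= 0, 1, -1)
            accs.append(accuracy(pred.astype(int), test.y))
    else:
        raise ValueError("mode must be 'fresh' or 'prefix'")
    return SweepResult(sizes=sizes, accuracies=accs)
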