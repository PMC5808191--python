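from __future__ import annotations

import numpy as np
import pytest

import rsvmcluster as rc


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced planted-effect cohort shared by ensemble/selection tests.

    30 regions, 16+16 subjects: small enough for repeated cluster
    builds, but carries a clearly detectable planted effect.
    """
    spec = rc.SimulationSpec(
        n_regions=30,
        n_timepoints=80,
        n_group_a=16,
        n_group_b=16,
        n_modules=5,
        n_planted_edges=10,
        effect_size=0.4,
        seed=7,
    )
    cohort = rc.generate_cohort(spec)
    X, fmap = rc.features_from_series(cohort.series)
    return cohort, cohort.labeled_dataset(X), fmap


@pytest.fixture(scope="session")
def small_split(small_cohort):
    _, ds, _ = small_cohort
    return rc.split_dataset(ds, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return rc.EnsembleConfig(
        n_classifiers=60, samples_per_svm=16, features_per_svm=30, seed=7
    )


@pytest.fixture(scope="session")
def small_cluster(small_split, small_config):
    return rc.build_cluster(small_split.train, small_config)


@pytest.fixture
def separable_dataset():
    """Two well-separated Gaussian clouds, trivially classifiable."""
    rng = np.random.default_rng(3)
    n, p = 40, 12
    X = rng.standard_normal((n, p))
    y = np.repeat([1, -1], n // 2)
    X[y == 1] += 6.0
    return rc.LabeledDataset(X, y)
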