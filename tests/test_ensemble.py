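"""Random SVM cluster training, voting, and the size sweep."""

import numpy as np
import pytest

import rsvmcluster as rc
from rsvmcluster.ensemble import base_votes


class TestTrainBaseSVM:
    def test_separable_two_points(self):
        ds = rc.LabeledDataset(np.array([[0.0, 0.0], [5.0, 5.0]]), [-1, 1])
        cfg = rc.EnsembleConfig(
            n_classifiers=1, samples_per_svm=2, features_per_svm=2, standardize=False
        )
        clf = rc.train_base_svm(ds, [0, 1], [0, 1], cfg)
        np.testing.assert_array_equal(clf.predict(ds.X), ds.y)

    def test_xor_pattern_fit_exactly_with_hard_margin(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        ds = rc.LabeledDataset(X, y)
        cfg = rc.EnsembleConfig(
            n_classifiers=1, samples_per_svm=4, features_per_svm=2, standardize=False
        )
        clf = rc.train_base_svm(ds, np.arange(4), [0, 1], cfg)
        np.testing.assert_array_equal(clf.predict(X), y)

    def test_single_class_subset_rejected(self):
        ds = rc.LabeledDataset(np.zeros((4, 2)), [1, 1, -1, -1])
        cfg = rc.EnsembleConfig(n_classifiers=1, samples_per_svm=2, features_per_svm=2)
        with pytest.raises(ValueError, match="single class"):
            rc.train_base_svm(ds, [0, 1], [0, 1], cfg)


class TestBuildCluster:
    def test_paper_default_subset_sizes(self, small_split):
        # paper protocol stores s=50 subject and f=62 feature indices
        cfg = rc.EnsembleConfig(n_classifiers=3, samples_per_svm=16, features_per_svm=62)
        cluster = rc.build_cluster(small_split.train, cfg)
        for clf in cluster.classifiers:
            assert clf.feature_indices.shape == (62,)
            assert len(set(clf.feature_indices.tolist())) == 62  # no replacement
            assert clf.sample_indices.shape == (16,)

    def test_same_seed_gives_identical_clusters(self, small_split, small_config):
        a = rc.build_cluster(small_split.train, small_config)
        b = rc.build_cluster(small_split.train, small_config)
        for ca, cb in zip(a.classifiers, b.classifiers):
            np.testing.assert_array_equal(ca.sample_indices, cb.sample_indices)
            np.testing.assert_array_equal(ca.feature_indices, cb.feature_indices)
        np.testing.assert_array_equal(
            rc.predict(a, small_split.test.X), rc.predict(b, small_split.test.X)
        )

    def test_cluster_of_one_behaves_as_single_svm(self, small_split):
        cfg = rc.EnsembleConfig(
            n_classifiers=1, samples_per_svm=16, features_per_svm=20, seed=5
        )
        cluster = rc.build_cluster(small_split.train, cfg)
        X_std = cluster.standardized(small_split.test.X)
        single = cluster.classifiers[0].predict(X_std)
        np.testing.assert_array_equal(rc.predict(cluster, small_split.test.X), single)

    def test_impossible_configurations_rejected(self, small_split):
        with pytest.raises(ValueError, match="samples_per_svm"):
            rc.build_cluster(
                small_split.train,
                rc.EnsembleConfig(n_classifiers=1, samples_per_svm=10_000,
                                  features_per_svm=5),
            )
        with pytest.raises(ValueError, match="features_per_svm"):
            rc.build_cluster(
                small_split.train,
                rc.EnsembleConfig(n_classifiers=1, samples_per_svm=5,
                                  features_per_svm=10_000),
            )

    def test_training_set_must_have_both_classes(self):
        ds = rc.LabeledDataset(np.random.default_rng(0).random((6, 4)),
                               np.ones(6, int))
        with pytest.raises(ValueError, match="both classes"):
            rc.build_cluster(ds, rc.EnsembleConfig(n_classifiers=1,
                                                   samples_per_svm=3,
                                                   features_per_svm=2))


class TestPredict:
    def test_unanimous_vote(self, separable_dataset):
        cfg = rc.EnsembleConfig(n_classifiers=9, samples_per_svm=20,
                                features_per_svm=6, seed=1)
        cluster = rc.build_cluster(separable_dataset, cfg)
        votes = base_votes(cluster, separable_dataset.X)
        unanimous = np.all(votes == votes[0], axis=0)
        pred = rc.predict(cluster, separable_dataset.X)
        np.testing.assert_array_equal(pred[unanimous], votes[0][unanimous])

    def test_vote_conservation(self, small_cluster, small_split):
        votes = base_votes(small_cluster, small_split.test.X)
        pos = (votes == 1).sum(axis=0)
        neg = (votes == -1).sum(axis=0)
        assert np.all(pos + neg == small_cluster.n_classifiers)

    def test_majority_equals_bruteforce_tally(self, small_cluster, small_split):
        votes = base_votes(small_cluster, small_split.test.X)
        pred = rc.predict(small_cluster, small_split.test.X)
        for j in range(votes.shape[1]):
            plus = int((votes[:, j] == 1).sum())
            minus = int((votes[:, j] == -1).sum())
            if plus != minus:
                assert pred[j] == (1 if plus > minus else -1)

    def test_even_split_tie_broken_by_decision_sum(self, separable_dataset):
        cfg = rc.EnsembleConfig(n_classifiers=2, samples_per_svm=10,
                                features_per_svm=4, seed=2)
        cluster = rc.build_cluster(separable_dataset, cfg)
        votes = base_votes(cluster, separable_dataset.X)
        pred = rc.predict(cluster, separable_dataset.X)
        X_std = cluster.standardized(separable_dataset.X)
        dec = sum(c.decision_values(X_std) for c in cluster.classifiers)
        tied = votes.sum(axis=0) == 0
        expect = np.where(dec >= 0, 1, -1)
        np.testing.assert_array_equal(pred[tied], expect[tied])

    def test_feature_count_mismatch_rejected(self, small_cluster):
        with pytest.raises(ValueError, match="features"):
            rc.predict(small_cluster, np.zeros((2, 3)))

    def test_label_symmetry_under_flip(self, separable_dataset):
        cfg = rc.EnsembleConfig(n_classifiers=7, samples_per_svm=20,
                                features_per_svm=6, seed=4)
        flipped = rc.LabeledDataset(
            separable_dataset.X, -separable_dataset.y,
            list(separable_dataset.subject_ids),
        )
        a = rc.predict(rc.build_cluster(separable_dataset, cfg), separable_dataset.X)
        b = rc.predict(rc.build_cluster(flipped, cfg), separable_dataset.X)
        np.testing.assert_array_equal(a, -b)


class TestAccuracy:
    def test_exact_match_fractions(self):
        assert rc.accuracy([1, -1, 1], [1, -1, 1]) == 1.0
        assert rc.accuracy([1, 1], [-1, -1]) == 0.0
        # 25 of 26 matches is the only multiple of 1/26 printing as 96.15%
        pred = np.ones(26, int)
        truth = np.ones(26, int)
        truth[0] = -1
        assert rc.accuracy(pred, truth) == pytest.approx(25 / 26)
        assert f"{rc.accuracy(pred, truth):.2%}" == "96.15%"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rc.accuracy([1, 1], [1])


class TestEvaluateBaseClassifiers:
    def test_per_classifier_accuracies_in_range(self, small_cluster, small_split):
        accs = rc.evaluate_base_classifiers(small_cluster, small_split.test)
        assert accs.shape == (small_cluster.n_classifiers,)
        assert np.all((accs >= 0) & (accs <= 1))

    def test_single_perfect_classifier(self, separable_dataset):
        cfg = rc.EnsembleConfig(n_classifiers=1, samples_per_svm=30,
                                features_per_svm=6, seed=0)
        cluster = rc.build_cluster(separable_dataset, cfg)
        accs = rc.evaluate_base_classifiers(cluster, separable_dataset)
        assert accs.tolist() == [1.0]

    def test_ensemble_beats_mean_base_on_separable_data(
        self, small_cluster, small_split
    ):
        base = rc.evaluate_base_classifiers(small_cluster, small_split.test)
        ens = rc.accuracy(
            rc.predict(small_cluster, small_split.test.X), small_split.test.y
        )
        assert ens >= base.mean()


class TestSizeSweep:
    def test_default_range_has_140_sizes(self):
        sizes = rc.default_size_range()
        assert len(sizes) == 140
        assert sizes[0] == 5 and sizes[-1] == 700 and sizes[1] - sizes[0] == 5

    def test_small_sweep_contract(self, small_split, small_config):
        res = rc.ensemble_size_sweep(
            small_split.train, small_split.test, small_config, sizes=[3, 7, 11]
        )
        assert len(res.accuracies) == 3
        assert all(0 <= a <= 1 for a in res.accuracies)
        again = rc.ensemble_size_sweep(
            small_split.train, small_split.test, small_config, sizes=[3, 7, 11]
        )
        assert res.accuracies == again.accuracies

    def test_single_size_is_optimal(self, small_split, small_config):
        res = rc.ensemble_size_sweep(
            small_split.train, small_split.test, small_config, sizes=[9]
        )
        assert res.optimal_size == 9

    def test_optimal_is_smallest_maximizer(self):
        res = rc.SweepResult(sizes=[5, 10, 15], accuracies=[0.8, 0.9, 0.9])
        assert res.optimal_size == 10

    def test_prefix_mode_runs(self, small_split, small_config):
        res = rc.ensemble_size_sweep(
            small_split.train, small_split.test, small_config,
            sizes=[5, 15, 25], mode="prefix",
        )
        assert len(res.accuracies) == 3
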