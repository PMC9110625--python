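"""AdaBoost primitives, the annealed-SVM boosting loop, feature selection,
LOSOCV and the one-vs-rest multiclass wrapper."""

import numpy as np
import pytest

from poseface import ensemble as ens
from poseface import synthetic
from poseface.errors import InvalidInputError, InvalidParameterError


def binary_dataset(seed=42, n=20, dim=2, sep=5.0, **kw):
    X, y, subj = synthetic.make_classification_data(
        n_per_class=n, dim=dim, separation=sep, noise=1.0, n_classes=2,
        seed=seed, **kw
    )
    return ens.LabeledDataset(X, np.where(y == 1, 1, -1), subj)


class TestWeights:
    def test_balanced_init(self):
        data = ens.LabeledDataset(np.zeros((10, 1)), np.array([1] * 5 + [-1] * 5))
        w = ens.init_weights(data)
        assert np.allclose(w, 0.1)

    def test_unbalanced_init_sums_to_one(self):
        y = np.array([1, 1] + [-1] * 8)
        data = ens.LabeledDataset(np.zeros((10, 1)), y)
        w = ens.init_weights(data)
        assert np.allclose(w[y == 1], 0.25)
        assert np.allclose(w[y == -1], 0.0625)
        assert w.sum() == pytest.approx(1.0, abs=1e-15)

    def test_empty_class_rejected(self):
        data = ens.LabeledDataset(np.zeros((2, 1)), np.array([1, 1]))
        with pytest.raises(InvalidInputError):
            ens.init_weights(data)

    def test_update_alpha_zero_is_identity(self, separable_blobs):
        w = ens.init_weights(separable_blobs)
        h = ens.train_weak(separable_blobs, w, delta=1.0)
        w2 = ens.update_weights(w, 0.0, h, separable_blobs)
        assert np.allclose(w2, w)

    def test_update_all_correct_uniform_stays_uniform(self, separable_blobs):
        w = np.full(separable_blobs.N, 1.0 / separable_blobs.N)
        h = ens.train_weak(separable_blobs, w, delta=1.0)
        assert ens.weighted_error(h, separable_blobs, w) == 0.0
        w2 = ens.update_weights(w, 0.7, h, separable_blobs)
        assert np.allclose(w2, w)

    def test_update_matches_per_sample_loop_oracle(self, separable_blobs, rng):
        data = separable_blobs
        w = rng.dirichlet(np.ones(data.N))
        h = ens.train_weak(data, w, delta=0.5)
        alpha_t = 0.4
        w2 = ens.update_weights(w, alpha_t, h, data)
        pred = h.predict(data.X)
        raw = np.array(
            [w[i] * np.exp(-alpha_t * data.y[i] * pred[i]) for i in range(data.N)]
        )
        assert np.allclose(w2, raw / raw.sum(), atol=1e-15)
        assert w2.sum() == pytest.approx(1.0, abs=1e-12)


class TestWeakClassifier:
    def test_separable_blobs_zero_error(self, separable_blobs):
        w = ens.init_weights(separable_blobs)
        h = ens.train_weak(separable_blobs, w, delta=1.0)
        assert h.xi == 0.0

    def test_uniform_weights_match_unweighted_fit(self, separable_blobs):
        from sklearn.svm import SVC

        data = separable_blobs
        w = np.full(data.N, 1.0 / data.N)
        h = ens.train_weak(data, w, delta=0.5, C=1.0)
        ref = SVC(C=1.0, kernel="rbf", gamma=1.0 / (2 * 0.5**2)).fit(data.X, data.y)
        grid = np.random.default_rng(0).normal(0, 3, size=(50, 2))
        assert np.array_equal(h.predict(grid), ref.predict(grid))

    def test_conflicting_duplicates_irreducible_error(self):
        X = np.zeros((4, 1))
        y = np.array([1, 1, 1, -1])
        data = ens.LabeledDataset(X, y)
        w = np.full(4, 0.25)
        h = ens.train_weak(data, w, delta=0.1)
        assert ens.weighted_error(h, data, w) >= 0.25 - 1e-12

    def test_weighted_error_range(self, separable_blobs):
        w = ens.init_weights(separable_blobs)
        h = ens.train_weak(separable_blobs, w, delta=1.0)
        xi = ens.weighted_error(h, separable_blobs, w)
        assert 0.0 <= xi <= 1.0

    def test_invalid_parameters(self, separable_blobs):
        w = ens.init_weights(separable_blobs)
        with pytest.raises(InvalidParameterError):
            ens.train_weak(separable_blobs, w, delta=-1.0)


class TestAlpha:
    def test_closed_forms(self):
        assert ens.alpha(0.5) == pytest.approx(0.0, abs=1e-9)
        assert ens.alpha(0.2) == pytest.approx(0.5 * np.log(4.0), abs=1e-9)

    def test_monotone_decreasing_on_grid(self):
        grid = np.linspace(0.01, 0.49, 100)
        vals = [ens.alpha(x) for x in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_boundaries_clipped_finite(self):
        assert np.isfinite(ens.alpha(0.0))
        assert ens.alpha(0.7) >= 0.0  # clipped into (0, 1/2)


class TestFit:
    def test_separable_fixture_reaches_zero_training_error(self, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=5).fit(seed=42)
        assert res.n_rounds <= 5
        assert res.training_error == 0.0

    def test_boosting_bound_holds(self):
        # overlapping classes so boosting actually runs several rounds
        data = binary_dataset(seed=3, sep=1.5)
        res = ens.AdaSVM(data=data, T=8).fit(seed=3)
        assert res.n_rounds >= 2
        assert res.training_error <= res.error_bound + 1e-12

    def test_weight_conservation_each_round(self):
        data = binary_dataset(seed=5, sep=1.0)
        res = ens.AdaSVM(data=data, T=6).fit(seed=5)
        for s in res.weight_sums:
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_alpha_positive_and_xi_below_half(self):
        data = binary_dataset(seed=9, sep=1.0)
        res = ens.AdaSVM(data=data, T=6).fit(seed=9)
        assert np.all(res.alphas > 0)
        assert np.all(res.xis < 0.5)

    def test_delta_log_non_increasing_bounded(self):
        data = binary_dataset(seed=11, sep=0.0)  # pure noise forces annealing
        schedule = ens.AnnealSchedule(delta_ini=10.0, delta_min=1.0, delta_step=2.0)
        res = ens.AdaSVM(data=data, schedule=schedule, T=3).fit(seed=11)
        log = np.array(res.delta_log)
        assert np.all(np.diff(log) <= 0)
        assert log.min() >= schedule.delta_min

    def test_label_noise_still_beats_majority_baseline(self):
        rng = np.random.default_rng(0)
        wins = 0
        for rep in range(10):
            X, y, subj = synthetic.make_classification_data(
                n_per_class=25, dim=2, separation=4.0, noise=1.0,
                n_classes=2, seed=100 + rep
            )
            yb = np.where(y == 1, 1, -1)
            flip = rng.random(len(yb)) < 0.10
            y_train = np.where(flip, -yb, yb)
            train = np.arange(len(yb)) % 2 == 0
            data = ens.LabeledDataset(X[train], y_train[train])
            res = ens.AdaSVM(data=data, T=5).fit(seed=rep)
            acc = np.mean(res.predict(X[~train]) == yb[~train])
            majority = max(np.mean(yb[~train] == 1), np.mean(yb[~train] == -1))
            wins += acc > majority
        assert wins >= 8

    def test_reproducible_given_data_and_seed(self, separable_blobs):
        r1 = ens.AdaSVM(data=separable_blobs, T=5).fit(seed=42)
        r2 = ens.AdaSVM(data=separable_blobs, T=5).fit(seed=42)
        grid = np.random.default_rng(1).normal(0, 3, size=(40, 2))
        assert np.array_equal(r1.predict(grid), r2.predict(grid))
        assert np.array_equal(r1.alphas, r2.alphas)

    def test_restart_mode_accepted(self):
        data = binary_dataset(seed=13, sep=1.0)
        res = ens.AdaSVM(data=data, T=3, on_chance_failure="restart").fit(seed=13)
        assert res.n_rounds >= 1

    def test_summary_renders(self, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=3).fit(seed=42)
        text = res.summary()
        assert "training error" in text and "alpha_t" in text


class TestPredict:
    def test_single_round_equals_weak_classifier(self, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=1).fit(seed=42)
        assert res.n_rounds == 1
        _, h = res.rounds[0]
        grid = np.random.default_rng(2).normal(0, 3, size=(30, 2))
        assert np.array_equal(res.predict(grid), h.predict(grid))

    def test_margin_zero_resolves_positive(self, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=1).fit(seed=42)
        res.rounds = []  # empty vote -> margin 0 everywhere
        assert np.all(res.predict(np.zeros((3, 2))) == 1)

    def test_training_samples_all_correct(self, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=5).fit(seed=42)
        assert np.array_equal(res.predict(separable_blobs.X), separable_blobs.y)

    def test_margins_returned(self, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=5).fit(seed=42)
        m = res.margin(separable_blobs.X)
        assert np.array_equal(np.where(m >= 0, 1, -1), res.predict(separable_blobs.X))


class TestSerialization:
    def test_round_trip_reproduces_predictions(self, tmp_path, separable_blobs):
        res = ens.AdaSVM(data=separable_blobs, T=3).fit(seed=42)
        res.save(tmp_path / "model")
        back = ens.load_results(tmp_path / "model")
        grid = np.random.default_rng(3).normal(0, 3, size=(50, 2))
        assert np.array_equal(back.predict(grid), res.predict(grid))
        assert np.array_equal(back.margin(grid), res.margin(grid))


class TestSelectFeatures:
    def test_single_round_picks_minimum_error_feature(self):
        data = binary_dataset(seed=21, dim=6, sep=5.0, n_informative=1)
        sel = ens.select_features(data, K=1, seed=21, max_rounds=1)
        assert sel == [0]

    def test_informative_dimensions_found(self):
        hits = 0
        for seed in range(8):
            data = binary_dataset(seed=seed, dim=10, sep=5.0, n_informative=2)
            sel = ens.select_features(data, K=3, seed=seed)
            hits += 0 in sel and 1 in sel
        assert hits >= 7

    def test_stump_mode(self):
        data = binary_dataset(seed=23, dim=10, sep=5.0, n_informative=2)
        sel = ens.select_features(data, K=3, seed=23, weak="stump")
        assert 0 in sel and 1 in sel

    def test_all_noise_returns_k_indices(self):
        data = binary_dataset(seed=25, dim=6, sep=0.0, n_informative=0)
        sel = ens.select_features(data, K=4, seed=25, weak="stump", max_rounds=6)
        assert len(sel) == 4
        assert len(set(sel)) == 4

    def test_k_larger_than_dimension_rejected(self, separable_blobs):
        with pytest.raises(InvalidParameterError):
            ens.select_features(separable_blobs, K=3)


class TestLosocv:
    def test_oracle_classifier_zero_error(self):
        # the true label is encoded in the feature, so the "oracle" reads it off
        y = np.array([0, 1, 2] * 4)
        X = y[:, None].astype(float)
        subj = np.repeat(np.arange(4), 3)
        rep = ens.losocv(X, y, subj,
                         lambda Xtr, ytr, str_, Xte: Xte[:, 0].astype(int))
        assert rep.error == 0.0
        assert rep.accuracy == 1.0

    def test_fold_count_equals_subjects(self):
        X = np.zeros((12, 1))
        y = np.array([1, -1] * 6)
        subj = np.repeat(np.arange(4), 3)
        rep = ens.losocv(X, y, subj, lambda a, b, c, Xte: np.ones(len(Xte)))
        assert len(rep.fold_ids) == 4
        assert sum(rep.fold_sizes) == 12

    def test_single_subject_rejected(self):
        with pytest.raises(InvalidInputError):
            ens.losocv(np.zeros((4, 1)), np.ones(4), np.zeros(4),
                       lambda *a: np.ones(1))

    def test_random_labels_near_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(32, 3))
            y = np.where(rng.random(32) < 0.5, 1, -1)
            subj = np.repeat(np.arange(4), 8)
            if len(np.unique(y)) < 2:
                continue

            def fit_predict(Xtr, ytr, str_, Xte):
                data = ens.LabeledDataset(Xtr, ytr)
                res = ens.AdaSVM(data=data, T=2).fit(seed=seed)
                return res.predict(Xte)

            accs.append(ens.losocv(X, y, subj, fit_predict).accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_misclassification_rate_matches_half_l1(self):
        """For +/-1 labels the error equals (1/(2n)) sum |f_i - y_i|."""
        y = np.array([1, -1, 1, -1])
        pred = np.array([1, 1, -1, -1])
        err = np.mean(pred != y)
        assert err == np.sum(np.abs(pred - y)) / (2 * len(y))


class TestMulticlass:
    def test_two_class_reduces_to_binary(self):
        data = binary_dataset(seed=31, sep=4.0)
        model = ens.MulticlassAdaSVM(data.X, data.y, data.subjects, T=3)
        res = model.fit(seed=31)
        bin_res = ens.AdaSVM(data=data, T=3).fit(seed=31)
        assert np.array_equal(res.predict(data.X) == 1, bin_res.predict(data.X) == 1)

    def test_three_gaussians_losocv(self):
        X, y, subj = synthetic.make_classification_data(
            n_per_class=15, dim=5, separation=5.0, noise=1.0, n_classes=3,
            subjects_per_class=3, seed=42,
        )

        def fit_predict(Xtr, ytr, str_, Xte):
            return ens.MulticlassAdaSVM(Xtr, ytr, str_, T=3).fit(seed=42).predict(Xte)

        rep = ens.losocv(X, y, subj, fit_predict)
        assert rep.accuracy >= 0.9

    def test_class_order_permutation_invariant(self):
        X, y, subj = synthetic.make_classification_data(
            n_per_class=10, dim=3, separation=5.0, noise=1.0, n_classes=3, seed=7,
        )
        r1 = ens.MulticlassAdaSVM(X, y, subj, T=2, classes=(0, 1, 2)).fit(seed=7)
        r2 = ens.MulticlassAdaSVM(X, y, subj, T=2, classes=(2, 0, 1)).fit(seed=7)
        p1, p2 = r1.predict(X), r2.predict(X)
        m1 = r1.margins(X)
        tied = np.sum(m1 == m1.max(axis=1, keepdims=True), axis=1) > 1
        assert np.array_equal(p1[~tied], p2[~tied])

    def test_absent_class_rejected(self):
        X = np.zeros((4, 1))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(InvalidInputError):
            ens.MulticlassAdaSVM(X, y, classes=(0, 1, 2))

    def test_confusion_matrix_rows_sum_to_counts(self):
        X, y, subj = synthetic.make_classification_data(
            n_per_class=8, dim=3, separation=5.0, noise=1.0, n_classes=3, seed=3,
        )

        def fit_predict(Xtr, ytr, str_, Xte):
            return ens.MulticlassAdaSVM(Xtr, ytr, str_, T=2).fit(seed=3).predict(Xte)

        rep = ens.losocv(X, y, subj, fit_predict)
        M = rep.confusion_matrix(np.unique(y))
        for i, c in enumerate(np.unique(y)):
            assert M[i].sum() == np.sum(y == c)


class TestSchedule:
    @pytest.mark.parametrize("bad", [(1.0, 2.0, 2.0), (1.0, 0.5, 1.0),
                                     (0.0, -1.0, 2.0)])
    def test_invalid_schedules_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            ens.AnnealSchedule(*bad)
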