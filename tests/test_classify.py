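"""SMOTE, distance-weighted KNN, subject-wise folds, cross-validation and the
incremental feature search."""

import numpy as np
import pandas as pd
import pytest

import gaitdx as g
import gaitdx.classify as cl
from gaitdx.errors import LeakageError, ParameterError


def point_on_some_segment(p, cloud, tol=1e-9):
    """True iff p lies on the segment between two distinct points of cloud."""
    for i in range(len(cloud)):
        for j in range(len(cloud)):
            if i == j:
                continue
            a, b = cloud[i], cloud[j]
            ab = b - a
            denom = np.dot(ab, ab)
            if denom == 0:
                continue
            t = np.dot(p - a, ab) / denom
            if -tol <= t <= 1 + tol and np.linalg.norm(p - (a + t * ab)) < tol:
                return True
    return False


class TestSmote:
    def test_balanced_input_returned_unchanged(self, rng):
        X = rng.standard_normal((90, 4))
        y = np.repeat(["a", "b", "c"], 30)
        Xa, ya = cl.smote_augment(X, y, seed=0)
        assert Xa.shape == X.shape
        np.testing.assert_array_equal(ya, y)

    def test_imbalanced_classes_filled_to_majority(self, rng):
        X = rng.standard_normal((21, 3))
        y = np.array(["ctrl"] * 6 + ["dn"] * 6 + ["dfu"] * 9)
        Xa, ya = cl.smote_augment(X, y, seed=1)
        _, counts = np.unique(ya, return_counts=True)
        assert set(counts) == {9}
        assert Xa.shape[0] == 27

    def test_synthetic_points_lie_on_same_class_segments(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array(["min"] * 10 + ["maj"] * 20)
        Xa, ya = cl.smote_augment(X, y, k=3, seed=2)
        synth = Xa[len(X):]
        assert np.all(ya[len(X):] == "min")
        minority = X[y == "min"]
        for p in synth:
            assert point_on_some_segment(p, minority)

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array(["a"] * 5 + ["b"] * 15)
        out1 = cl.smote_augment(X, y, seed=7)
        out2 = cl.smote_augment(X, y, seed=7)
        np.testing.assert_array_equal(out1[0], out2[0])

    def test_k_clamped_with_warning_and_singleton_rejected(self, rng):
        X = rng.standard_normal((8, 2))
        y = np.array(["a"] * 3 + ["b"] * 5)
        with pytest.warns(UserWarning, match="clamped"):
            cl.smote_augment(X, y, k=5, seed=0)
        y_bad = np.array(["a"] + ["b"] * 7)
        with pytest.raises(ParameterError):
            cl.smote_augment(X, y_bad, seed=0)


class TestKnn:
    def test_exact_match_wins_outright(self):
        train = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        y = np.array(["a", "b", "c"])
        labels, _ = cl.knn_predict(train, y, np.array([[1.0, 1.0]]), cl.KnnConfig(3))
        assert labels[0] == "b"

    def test_self_prediction_is_perfect(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.choice(["a", "b", "c"], 50)
        labels, _ = cl.knn_predict(X, y, X, cl.KnnConfig(1))
        np.testing.assert_array_equal(labels, y)

    def test_agreement_with_brute_force_oracle(self, rng):
        train = rng.standard_normal((120, 5))
        y = rng.choice(["a", "b", "c"], 120)
        test = rng.standard_normal((200, 5))
        for k, weighting in [(1, "squared-inverse"), (5, "inverse"), (7, "uniform")]:
            cfg = cl.KnnConfig(k, "euclidean", weighting)
            labels, _ = cl.knn_predict(train, y, test, cfg)
            classes = np.unique(y)
            for i, p in enumerate(test):
                d = np.sqrt(((train - p) ** 2).sum(axis=1))
                nn = np.argsort(d, kind="stable")[:k]
                w = {"uniform": np.ones(k), "inverse": 1 / (d[nn] + 1e-12),
                     "squared-inverse": 1 / (d[nn] ** 2 + 1e-12)}[weighting]
                votes = {c: w[y[nn] == c].sum() for c in classes}
                expected = max(classes, key=lambda c: votes[c])
                assert labels[i] == expected

    def test_weighting_inert_at_k1(self, rng):
        train = rng.standard_normal((60, 3))
        y = rng.choice(["a", "b"], 60)
        test = rng.standard_normal((40, 3))
        preds = [
            cl.knn_predict(train, y, test, cl.KnnConfig(1, "euclidean", w))[0]
            for w in ("uniform", "inverse", "squared-inverse")
        ]
        np.testing.assert_array_equal(preds[0], preds[1])
        np.testing.assert_array_equal(preds[0], preds[2])

    def test_k_exceeding_train_size_rejected(self, rng):
        with pytest.raises(ParameterError):
            cl.knn_predict(rng.standard_normal((3, 2)), ["a", "b", "a"],
                           rng.standard_normal((1, 2)), cl.KnnConfig(5))

    def test_scores_are_normalized(self, rng):
        train = rng.standard_normal((30, 3))
        y = rng.choice(["a", "b", "c"], 30)
        test = rng.standard_normal((20, 3))
        for k in (1, 5):
            _, scores = cl.knn_predict(train, y, test, cl.KnnConfig(k))
            np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)


class TestFolds:
    def test_21_subjects_dealt_into_balanced_folds(self):
        subjects = {f"C{i}": "control" for i in range(6)}
        subjects.update({f"N{i}": "DN" for i in range(6)})
        subjects.update({f"U{i}": "DFU" for i in range(9)})
        fa = cl.subject_wise_folds(subjects, 5, seed=3)
        sizes = np.bincount(list(fa.fold_of.values()), minlength=5)
        assert sizes.sum() == 21
        assert set(sizes) <= {4, 5}

    def test_records_of_a_subject_share_a_fold(self):
        subjects = {f"s{i}": ("DN" if i % 2 else "control") for i in range(10)}
        fa = cl.subject_wise_folds(subjects, 5, seed=0)
        ids = np.array([f"s{i % 10}" for i in range(100)])
        rf = fa.record_folds(ids)
        for s in subjects:
            assert len(set(rf[ids == s])) == 1

    def test_train_test_subjects_disjoint_per_fold(self):
        subjects = {f"s{i}": ("DN" if i % 2 else "control") for i in range(10)}
        fa = cl.subject_wise_folds(subjects, 5, seed=1)
        ids = np.array(sorted(subjects) * 4)
        rf = fa.record_folds(ids)
        for fold in range(5):
            assert not (set(ids[rf == fold]) & set(ids[rf != fold]))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(Exception):
            cl.subject_wise_folds({"a": "control", "b": "DN"}, 5, seed=0)


def _toy_table(rng, n_per=30, sep=6.0):
    """Three trivially separable classes with subject structure."""
    y = np.repeat(["a", "b", "c"], n_per)
    X = np.vstack(
        [rng.normal(m, 0.3, size=(n_per, 3)) for m in (0.0, sep, 2 * sep)]
    )
    subs = np.concatenate(
        [[f"{lab}{i % 3}" for i in range(n_per)] for lab in ("a", "b", "c")]
    )
    table = pd.DataFrame(X, columns=["f1", "f2", "f3"])
    return table, y, subs


class TestCrossValidation:
    def test_separable_classes_reach_perfect_accuracy(self, rng):
        table, y, subs = _toy_table(rng)
        fa = cl.subject_wise_folds(dict(zip(subs, y)), 3, seed=0)
        report = cl.cross_validated_run(table, y, fa.record_folds(subs), seed=0, subject_ids=subs)
        assert report.accuracy == pytest.approx(100.0)

    def test_deterministic_given_data_folds_seed(self, rng):
        table, y, subs = _toy_table(rng)
        fa = cl.subject_wise_folds(dict(zip(subs, y)), 3, seed=0)
        rf = fa.record_folds(subs)
        a = cl.cross_validated_run(table, y, rf, seed=5, subject_ids=subs)
        b = cl.cross_validated_run(table, y, rf, seed=5, subject_ids=subs)
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.confusion.counts, b.confusion.counts)

    def test_subject_straddling_folds_raises_leakage_error(self, rng):
        table, y, subs = _toy_table(rng)
        bad_folds = (np.arange(len(y)) // 2) % 3  # splits each subject across folds
        with pytest.raises(LeakageError):
            cl.cross_validated_run(table, y, bad_folds, seed=0, subject_ids=subs)

    def test_empty_test_fold_rejected(self, rng):
        table, y, subs = _toy_table(rng)
        folds = np.zeros(len(y), dtype=int)  # a single fold: train side empty
        with pytest.raises(ParameterError):
            cl.cross_validated_run(table, y, folds, seed=0)


class TestIncrementalSearch:
    def test_smallest_argmax_rule(self):
        assert cl.best_k_from_trace([0.5, 0.9, 0.9]) == 2
        assert cl.best_k_from_trace([0.7]) == 1

    def test_trace_matches_independent_reruns(self, rng):
        table, y, subs = _toy_table(rng)
        fa = cl.subject_wise_folds(dict(zip(subs, y)), 3, seed=0)
        rf = fa.record_folds(subs)
        ranked = g.rank_chi2(table, y)
        result = cl.incremental_feature_search(ranked, table, y, rf, seed=2, subject_ids=subs)
        for k in (1, 2, 3):
            rerun = cl.cross_validated_run(
                table[ranked.names[:k]], y, rf, seed=2, subject_ids=subs
            )
            assert result.per_k.loc[k - 1, "accuracy"] == pytest.approx(rerun.accuracy)

    def test_single_feature_list_gives_k1(self, rng):
        table, y, subs = _toy_table(rng)
        fa = cl.subject_wise_folds(dict(zip(subs, y)), 3, seed=0)
        ranked = g.RankedFeatureList("chi2", ["f1"], np.array([1.0]))
        result = cl.incremental_feature_search(ranked, table, y, fa.record_folds(subs), seed=0, subject_ids=subs)
        assert result.best_k == 1


def test_grid_search_returns_best_config_on_separable_data(rng):
    table, y, subs = _toy_table(rng, n_per=15)
    fa = cl.subject_wise_folds(dict(zip(subs, y)), 3, seed=0)
    cfg, grid = cl.grid_search_knn(
        table, y, fa.record_folds(subs), seed=0, subject_ids=subs,
        n_neighbors_grid=(1, 3), metrics=("euclidean",),
        weightings=("uniform", "squared-inverse"),
    )
    assert grid.shape[0] == 4
    assert grid["accuracy"].max() == grid.loc[
        (grid["n_neighbors"] == cfg.n_neighbors)
        & (grid["weighting"] == cfg.weighting), "accuracy"
    ].iloc[0]
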