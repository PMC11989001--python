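"""Splits, the printed accuracy/precision formulas, the model registry."""

import numpy as np
import pandas as pd
import pytest

from alliumcw import mlclass


def separable_table(n_per_class=10, n_features=4, sep=50.0, noise=1.0, seed=0):
    """Three layer classes with means ``sep`` apart: >> 5 sigma separation."""
    rng = np.random.default_rng(seed)
    rows = []
    for k, layer in enumerate(("S1", "S2", "S6")):
        X = rng.normal(k * sep, noise, size=(n_per_class, n_features))
        for i in range(n_per_class):
            rows.append({"sample_id": f"{layer}_{i}", "layer": layer,
                         **{f"f{j}": X[i, j] for j in range(n_features)}})
    return pd.DataFrame(rows)


class TestSplit:
    def test_stratified_counts(self):
        train, test = mlclass.split_train_test(separable_table(10), 0.7, seed=1)
        assert len(train) == 21 and len(test) == 9
        assert (train["layer"].value_counts() == 7).all()
        assert (test["layer"].value_counts() == 3).all()

    def test_deterministic_and_partitioning(self):
        t = separable_table(10)
        tr1, te1 = mlclass.split_train_test(t, seed=5)
        tr2, te2 = mlclass.split_train_test(t, seed=5)
        pd.testing.assert_frame_equal(tr1, tr2)
        ids = set(tr1["sample_id"]) | set(te1["sample_id"])
        assert ids == set(t["sample_id"])
        assert not set(tr1["sample_id"]) & set(te1["sample_id"])

    def test_test_membership_frequency(self):
        t = separable_table(10)
        counts = {s: 0 for s in t["sample_id"]}
        n_seeds = 3000
        for seed in range(n_seeds):
            _, test = mlclass.split_train_test(t, 0.7, seed=seed)
            for s in test["sample_id"]:
                counts[s] += 1
        freqs = np.array(list(counts.values())) / n_seeds
        assert np.all(np.abs(freqs - 0.3) < 0.03)

    def test_singleton_class_rejected(self):
        t = separable_table(2)
        t = t.drop(t[t.layer == "S6"].index[1:])
        with pytest.raises(ValueError, match="stratify"):
            mlclass.split_train_test(t)


class TestMetricFormulas:
    def test_printed_examples(self):
        assert mlclass.classification_accuracy(9, 9, 1, 1) == 0.9
        assert mlclass.classification_accuracy(0, 10, 0, 0) == 1.0
        assert mlclass.precision_score(8, 2) == 0.8
        assert mlclass.precision_score(5, 0) == 1.0

    def test_undefined_metrics_raise(self):
        with pytest.raises(ValueError):
            mlclass.classification_accuracy(0, 0, 0, 0)
        with pytest.raises(ValueError):
            mlclass.precision_score(0, 0)

    def test_formulas_match_label_pair_recount(self):
        # binary labels: formula counts vs direct fraction agreement, exactly
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(4, 40)
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            tp = int(np.sum((y_true == 1) & (y_pred == 1)))
            tn = int(np.sum((y_true == 0) & (y_pred == 0)))
            fp = int(np.sum((y_true == 0) & (y_pred == 1)))
            fn = int(np.sum((y_true == 1) & (y_pred == 0)))
            assert mlclass.classification_accuracy(tp, tn, fp, fn) == \
                np.mean(y_true == y_pred)
            if tp + fp > 0:
                assert mlclass.precision_score(tp, fp) == tp / (tp + fp)

    def test_macro_precision_matches_brute_force(self):
        rng = np.random.default_rng(1)
        classes = np.array(["S1", "S2", "S6"])
        y_true = rng.choice(classes, 300)
        y_pred = rng.choice(classes, 300)
        _, macro, weighted, _ = mlclass.evaluate_predictions(y_true, y_pred)
        per_class = []
        for c in classes:
            tp = np.sum((y_true == c) & (y_pred == c))
            fp = np.sum((y_true != c) & (y_pred == c))
            per_class.append(tp / (tp + fp) if tp + fp else 0.0)
        assert macro == pytest.approx(np.mean(per_class), abs=1e-12)
        supports = [np.sum(y_true == c) for c in classes]
        assert weighted == pytest.approx(
            np.average(per_class, weights=supports), abs=1e-12)

    def test_ca_from_confusion_equals_pairwise(self):
        rng = np.random.default_rng(2)
        y_true = rng.choice(["S1", "S2", "S6"], 200)
        y_pred = rng.choice(["S1", "S2", "S6"], 200)
        counts = mlclass.confusion_counts(y_true, y_pred)
        ca, *_ = mlclass.evaluate_predictions(y_true, y_pred)
        assert ca == np.trace(counts.to_numpy()) / 200
        assert ca == np.mean(y_true == y_pred)


class TestModelSuite:
    def test_separable_data_perfect_for_all_models(self):
        reports = mlclass.run_model_suite(
            separable_table(10), seed=3, importance=False)
        assert len(reports) == 7
        for r in reports:
            assert r.ca == 1.0, r.model
            assert np.allclose(r.confusion_percent.sum(axis=1), 100.0)

    def test_reports_sorted_by_ca(self):
        reports = mlclass.run_model_suite(
            separable_table(8, noise=60.0), seed=4, importance=False)
        cas = [r.ca for r in reports]
        assert cas == sorted(cas, reverse=True)

    def test_duplicate_feature_leaves_svm_unchanged(self):
        t = separable_table(10, noise=30.0, seed=5)
        t2 = t.assign(f_dup=t["f0"])
        r1 = mlclass.run_model_suite(t, ("svm",), seed=6, importance=False)[0]
        r2 = mlclass.run_model_suite(t2, ("svm",), seed=6, importance=False)[0]
        # duplicated standardized feature only reweights the kernel slightly;
        # on well-separated data the predictions are identical
        assert r1.ca == pytest.approx(r2.ca, abs=1e-6)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError, match="registry"):
            mlclass.run_model_suite(separable_table(5), ("svm", "xgboost"))

    def test_missing_values_rejected(self):
        t = separable_table(5)
        t.loc[0, "f0"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mlclass.run_model_suite(t, ("svm",))


class TestFeatureImportance:
    def test_planted_signal_dominates(self):
        rng = np.random.default_rng(7)
        n = 60
        layers = np.repeat(["S1", "S2", "S6"], n // 3)
        informative = pd.Categorical(layers).codes * 10.0 + rng.normal(0, 1, n)
        t = pd.DataFrame({"layer": layers, "signal": informative})
        for j in range(9):
            t[f"noise{j}"] = rng.normal(0, 1, n)
        X, y, names = mlclass._split_features(t)
        model = mlclass.make_model("svm", seed=0)
        model.fit(X, y)
        shares = mlclass.feature_importance(model, X, y, names, seed=0)
        assert shares["signal"] > 0.8

    def test_single_feature_convention(self):
        assert mlclass.feature_importance(None, None, None, ["only"]) == \
            {"only": 1.0}

    def test_null_features_no_dominant_share(self):
        # all-noise features, shuffled labels: the SVM's importances must
        # not concentrate on any single feature
        rng = np.random.default_rng(8)
        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            n = 30
            t = pd.DataFrame({
                "layer": rng.permutation(np.repeat(["S1", "S2", "S6"], n // 3)),
                **{f"x{j}": rng.normal(0, 1, n) for j in range(10)},
            })
            X, y, names = mlclass._split_features(t)
            model = mlclass.make_model("svm", seed=seed)
            model.fit(X, y)
            shares = mlclass.feature_importance(model, X, y, names,
                                                seed=seed, n_repeats=10)
            wins += max(shares.values()) > 0.5
        assert wins / n_seeds <= 0.05
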