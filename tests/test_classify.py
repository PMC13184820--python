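import numpy as np
import pandas as pd
import pytest

from glycopore import classify as cl
from glycopore.features import FEATURE_NAMES
from glycopore.trace_io import ValidationError


def blob_table(centers, n=100, sd=0.3, seed=0, features=("mean", "std", "dwell_time")):
    """Small labelled feature tables with Gaussian-blob structure."""
    rng = np.random.default_rng(seed)
    tables = {}
    for label, center in centers.items():
        df = pd.DataFrame({f: np.nan for f in FEATURE_NAMES}, index=range(n))
        for j, f in enumerate(features):
            df[f] = rng.normal(center[j], sd, n)
        for f in FEATURE_NAMES:
            if f not in features:
                df[f] = rng.normal(0, 1, n)
        tables[label] = df
    return tables


class TestAssembleDataset:
    def test_70_15_15_split_counts(self, rng):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5]}, n=1000)
        data, split = cl.assemble_dataset(tables, 1000, seed=0)
        assert len(split.train) == 1400
        assert len(split.validation) == 300
        assert len(split.test) == 300

    def test_per_class_train_fraction(self):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5], "c": [9, 9, 9]}, n=400)
        data, split = cl.assemble_dataset(tables, 400, seed=1)
        for label in tables:
            in_train = (data.iloc[split.train]["label"] == label).sum()
            assert abs(in_train - 0.70 * 400) <= 1

    def test_sets_are_disjoint_and_exhaustive(self):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5]}, n=333)
        data, split = cl.assemble_dataset(tables, 333, seed=2)
        all_idx = np.concatenate([split.train, split.validation, split.test])
        assert len(set(all_idx)) == len(all_idx) == len(data)

    def test_deterministic_under_seed(self):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5]})
        _, s1 = cl.assemble_dataset(tables, 100, seed=11)
        _, s2 = cl.assemble_dataset(tables, 100, seed=11)
        np.testing.assert_array_equal(s1.train, s2.train)

    def test_subsampling_caps_class_size(self):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5]}, n=500)
        data, _ = cl.assemble_dataset(tables, 200, seed=3)
        assert (data["label"] == "a").sum() == 200

    def test_empty_class_rejected(self):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5]})
        tables["c"] = tables["a"].iloc[:0]
        with pytest.raises(ValidationError):
            cl.assemble_dataset(tables, 100, seed=0)


class TestAnovaRanking:
    def test_hand_computed_f_value(self):
        """F equals the textbook between/within mean-square ratio on a 2×3 table."""
        train = pd.DataFrame({f: np.nan for f in FEATURE_NAMES}, index=range(6))
        x = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        train["mean"] = x
        train["label"] = ["a"] * 3 + ["b"] * 3
        # standardized values keep the F ratio; compute it directly:
        z = (x - x.mean()) / x.std()
        groups = [z[:3], z[3:]]
        grand = z.mean()
        msb = sum(3 * (g.mean() - grand) ** 2 for g in groups) / 1
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / 4
        ranked = cl.rank_features_anova(train, feature_names=["mean"])
        assert ranked.loc[0, "F"] == pytest.approx(msb / msw)

    def test_uninformative_feature_ranked_last(self, rng):
        tables = blob_table({"a": [0, 0, 5], "b": [5, 5, 5]}, n=200)
        train = pd.concat(
            [t.assign(label=l) for l, t in tables.items()], ignore_index=True
        )
        ranked = cl.rank_features_anova(train)
        # dwell_time was identical across classes (center 5 both)
        assert ranked[ranked["feature"] == "mean"].index[0] < \
               ranked[ranked["feature"] == "dwell_time"].index[0]

    def test_zero_within_class_variance_flagged_first(self):
        train = pd.DataFrame({f: 0.0 for f in FEATURE_NAMES}, index=range(8))
        train["mean"] = [1.0] * 4 + [2.0] * 4
        for f in FEATURE_NAMES:
            if f != "mean":
                train[f] = np.random.default_rng(0).normal(0, 1, 8)
        train["label"] = ["a"] * 4 + ["b"] * 4
        ranked = cl.rank_features_anova(train)
        assert ranked.loc[0, "feature"] == "mean"
        assert ranked.loc[0, "degenerate"]


class TestTopK:
    def test_selects_k(self, trained_setup):
        assert len(cl.select_top_k(trained_setup["ranked"], 12)) == 12

    def test_named_informative_features_present(self, trained_setup):
        selected = cl.select_top_k(trained_setup["ranked"], 12)
        assert {"std", "mean", "median"} <= set(selected)

    def test_k_equals_all_is_identity(self, trained_setup):
        assert cl.select_top_k(trained_setup["ranked"], 19) == \
               trained_setup["ranked"]["feature"].tolist()

    @pytest.mark.parametrize("k", [0, 25])
    def test_degenerate_k_rejected(self, trained_setup, k):
        with pytest.raises(ValidationError):
            cl.select_top_k(trained_setup["ranked"], k)


class TestPreprocessor:
    def test_no_missingness_no_indicators(self, rng):
        train = pd.DataFrame({"mean": rng.normal(5, 1, 100), "std": rng.normal(2, 1, 100)})
        pp = cl.fit_preprocessor(train, ["mean", "std"])
        assert pp.indicator_features == []
        X = cl.apply_preprocessor(pp, train)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0), 1, atol=1e-12)

    def test_test_missingness_uses_train_median(self, rng):
        train = pd.DataFrame({"mean": [1.0, 2.0, 3.0, np.nan]})
        pp = cl.fit_preprocessor(train, ["mean"])
        test = pd.DataFrame({"mean": [np.nan]})
        X = cl.apply_preprocessor(pp, test)
        # imputed value standardizes like the train median; indicator is 1
        train_imputed = cl.apply_preprocessor(pp, pd.DataFrame({"mean": [2.0]}))
        assert X[0, 0] == pytest.approx(train_imputed[0, 0])
        assert X[0, 1] == X[:, 1].max()  # indicator column fires

    def test_refit_reproduces_transform(self, trained_setup):
        pp2 = cl.fit_preprocessor(trained_setup["train"], trained_setup["selected"])
        X1 = cl.apply_preprocessor(trained_setup["preprocessor"], trained_setup["test"])
        X2 = cl.apply_preprocessor(pp2, trained_setup["test"])
        np.testing.assert_array_equal(X1, X2)

    def test_fingerprint_ties_to_training_rows(self, trained_setup):
        """No-leakage check: the fitted state is a pure function of train rows."""
        pp = trained_setup["preprocessor"]
        other = cl.fit_preprocessor(trained_setup["validation"], trained_setup["selected"])
        assert pp.train_fingerprint != other.train_fingerprint

    def test_missing_selected_feature_rejected(self, trained_setup):
        with pytest.raises(ValidationError):
            cl.apply_preprocessor(trained_setup["preprocessor"],
                                  pd.DataFrame({"mean": [1.0]}))


class TestDenoise:
    def test_clean_blobs_mostly_retained(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (500, 3)), rng.normal(5, 0.3, (500, 3))])
        retained = cl.denoise_training(X)
        assert retained.size >= 0.99 * 1000

    def test_planted_uniform_background_dropped(self, rng):
        blobs = np.vstack([rng.normal(0, 0.25, (500, 3)), rng.normal(5, 0.25, (500, 3))])
        noise = rng.uniform(-10, 15, (50, 3))
        X = np.vstack([blobs, noise])
        retained = set(cl.denoise_training(X).tolist())
        blob_kept = sum(i in retained for i in range(1000)) / 1000
        noise_kept = sum(i in retained for i in range(1000, 1050)) / 50
        assert blob_kept >= 0.95
        assert noise_kept < 0.5

    def test_deterministic(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (300, 3)), rng.normal(4, 0.3, (300, 3))])
        np.testing.assert_array_equal(cl.denoise_training(X), cl.denoise_training(X))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            cl.denoise_training(np.array([[np.nan, 1.0]]))


class TestModelEvaluation:
    def test_separable_classes_near_perfect(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (200, 4)), rng.normal(3, 0.2, (200, 4))])
        y = np.repeat([0, 1], 200)
        zoo = {"lda": cl.default_model_zoo(0)["lda"]}
        report = cl.evaluate_models(X, y, zoo=zoo, n_splits=5, n_repeats=1)
        assert report.metrics["lda"]["accuracy"][0] > 0.99

    def test_permuted_labels_fall_to_chance(self, rng):
        """Label permutation drives accuracy to 1/K (4 classes → 0.25)."""
        X = rng.normal(0, 1, (800, 5))
        y = rng.integers(0, 4, 800)  # labels independent of X
        zoo = {k: v for k, v in cl.default_model_zoo(0).items() if k in ("lda", "gaussian_nb")}
        report = cl.evaluate_models(X, y, zoo=zoo, n_splits=5, n_repeats=1)
        se = np.sqrt(0.25 * 0.75 / 800)
        for name in zoo:
            assert abs(report.metrics[name]["accuracy"][0] - 0.25) < 5 * se

    def test_winner_is_argmax_macro_f1(self, rng):
        X = np.vstack([rng.normal(0, 1.0, (150, 3)), rng.normal(1, 1.0, (150, 3))])
        y = np.repeat([0, 1], 150)
        zoo = {k: v for k, v in cl.default_model_zoo(0).items() if k in ("lda", "knn")}
        report = cl.evaluate_models(X, y, zoo=zoo, n_splits=4, n_repeats=1)
        best = max(report.metrics, key=lambda k: report.metrics[k]["macro_f1"][0])
        assert report.chosen == best

    def test_zoo_contains_required_models(self):
        zoo = cl.default_model_zoo(0)
        assert {"mlp", "random_forest", "gradient_boosting", "svc", "lda"} <= set(zoo)
        assert len(zoo) == 10


class TestFinalModel:
    @pytest.fixture(scope="class")
    def bundle(self):
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5], "c": [0, 5, 0]}, n=200, seed=4)
        data, split = cl.assemble_dataset(tables, 200, seed=4)
        train = data.iloc[split.train]
        selected = ["mean", "std", "dwell_time"]
        bundle = cl.train_final(train, selected, seed=0,
                                model=cl.default_model_zoo(0)["random_forest"])
        return bundle, data.iloc[split.test]

    def test_separable_training_data_memorized(self, bundle):
        b, test = bundle
        labels, proba = cl.predict_events(b, test)
        assert (labels == test["label"].to_numpy()).mean() > 0.99
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_serialization_round_trip(self, bundle, tmp_path):
        b, test = bundle
        cl.save_bundle(b, tmp_path / "bundle")
        loaded = cl.load_bundle(tmp_path / "bundle")
        l1, p1 = cl.predict_events(b, test)
        l2, p2 = cl.predict_events(loaded, test)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)

    def test_schema_mismatch_rejected(self, bundle):
        b, _ = bundle
        with pytest.raises(ValidationError):
            cl.predict_events(b, pd.DataFrame({"mean": [0.0]}))

    def test_unknown_selected_feature_rejected(self, bundle):
        _, test = bundle
        with pytest.raises(ValidationError):
            cl.train_final(test.assign(label="a"), ["nonexistent_feature"], seed=0)

    def test_confusion_matrix_rows_sum_to_one(self, bundle):
        b, test = bundle
        cm, _ = cl.confusion_and_learning_curve(b, test)
        np.testing.assert_allclose(cm.sum(axis=1), 1.0)
        assert np.trace(cm.to_numpy()) > 2.9  # near-identity for separable data

    def test_learning_curve_improves_on_separable_data(self, bundle):
        b, test = bundle
        tables = blob_table({"a": [0, 0, 0], "b": [5, 5, 5], "c": [0, 5, 0]}, n=200, seed=4)
        data, split = cl.assemble_dataset(tables, 200, seed=4)
        _, curve = cl.confusion_and_learning_curve(
            b, test, train=data.iloc[split.train], sizes=(0.2, 0.6, 1.0), cv=3
        )
        assert curve["cv_score"].iloc[-1] >= curve["cv_score"].iloc[0] - 0.02


class TestEmbedding:
    def test_shape_determinism_and_separation(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (60, 5)), rng.normal(4, 0.3, (60, 5))])
        y = np.repeat([0, 1], 60)
        e1 = cl.embed_2d(X, seed=3)
        e2 = cl.embed_2d(X, seed=3)
        assert e1.shape == (120, 2)
        np.testing.assert_allclose(e1, e2, atol=1e-5)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(e1, y) > 0
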