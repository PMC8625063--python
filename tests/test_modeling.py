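import numpy as np
import pandas as pd
import pytest

import shankpose as sp
from shankpose.io_formats import ValidationError
from shankpose.modeling import DEFAULT_GRIDS, confusion_counts, stage_seed


def toy_matrix(counts: dict[str, int], seed=0, n_features=6, sep=4.0) -> pd.DataFrame:
    """Separable Gaussian blobs, one per class, as a feature matrix."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i, (label, n) in enumerate(counts.items()):
        center = np.zeros(n_features)
        center[i % n_features] = sep
        rows.append(rng.normal(size=(n, n_features)) + center)
        labels += [label] * n
    df = pd.DataFrame(np.vstack(rows), columns=[f"f{j}" for j in range(n_features)])
    df["label"] = labels
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


BALANCED_200 = {c: 200 for c in sp.MERGED_LABELS}


class TestFScores:
    def test_perfect_predictions(self):
        y = ["sitting", "standing", "stepping", "lying"] * 5
        out = sp.f_scores(y, y)
        assert out["weighted_f"] == pytest.approx(1.0)
        assert all(v["f"] == 1.0 for v in out["per_class"].values())

    def test_manual_arithmetic_tp9_fp1_fn1(self):
        # sitting: TP=9, FP=1, FN=1 -> P = R = F = 0.9
        y_true = ["sitting"] * 10 + ["standing"] * 10
        y_pred = ["sitting"] * 9 + ["standing"] + ["sitting"] + ["standing"] * 9
        out = sp.f_scores(y_true, y_pred)
        assert out["per_class"]["sitting"]["precision"] == pytest.approx(0.9)
        assert out["per_class"]["sitting"]["recall"] == pytest.approx(0.9)
        assert out["per_class"]["sitting"]["f"] == pytest.approx(0.9)
        assert out["weighted_f"] == pytest.approx(0.9)

    def test_absent_class_scores_zero_with_zero_support(self):
        y_true = ["sitting"] * 4
        y_pred = ["sitting"] * 4
        out = sp.f_scores(y_true, y_pred)
        assert out["per_class"]["lying"] == {
            "precision": 0.0, "recall": 0.0, "f": 0.0, "support": 0
        }
        assert out["weighted_f"] == pytest.approx(1.0)

    def test_weighted_f_is_support_weighted_mean(self):
        rng = np.random.default_rng(5)
        y_true = rng.choice(sp.MERGED_LABELS, size=200)
        y_pred = rng.choice(sp.MERGED_LABELS, size=200)
        out = sp.f_scores(y_true, y_pred)
        manual = sum(
            v["support"] / 200 * v["f"] for v in out["per_class"].values()
        )
        assert out["weighted_f"] == pytest.approx(manual, abs=1e-9)

    def test_matches_sklearn_weighted_f1(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(9)
        y_true = rng.choice(sp.MERGED_LABELS, size=300)
        y_pred = rng.choice(sp.MERGED_LABELS, size=300)
        ours = sp.f_scores(y_true, y_pred)["weighted_f"]
        theirs = f1_score(y_true, y_pred, average="weighted")
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            sp.f_scores([], [])


class TestConfusion:
    def test_perfect_diagonal(self):
        y = list(sp.MERGED_LABELS) * 3
        conf = sp.confusion(y, y)
        np.testing.assert_allclose(np.diag(conf.to_numpy()), 100.0)
        np.testing.assert_allclose(conf.to_numpy().sum(axis=1), 100.0)

    def test_all_sitting_predicted_standing(self):
        conf = sp.confusion(["sitting"] * 5, ["standing"] * 5)
        np.testing.assert_allclose(
            conf.loc["sitting"].to_numpy(), [0.0, 100.0, 0.0, 0.0]
        )

    def test_count_and_normalize(self):
        y_true = ["sitting"] * 10
        y_pred = ["sitting"] * 8 + ["lying"] * 2
        conf = sp.confusion(y_true, y_pred)
        assert conf.loc["sitting", "sitting"] == pytest.approx(80.0)
        assert conf.loc["sitting", "lying"] == pytest.approx(20.0)

    def test_absent_true_class_row_is_nan(self):
        conf = sp.confusion(["sitting"] * 5, ["sitting"] * 5)
        assert conf.loc["lying"].isna().all()
        assert conf.loc["sitting", "sitting"] == pytest.approx(100.0)


class TestBalanceClasses:
    def test_downsample_to_minority(self):
        mat = toy_matrix({"sitting": 50, "standing": 30, "stepping": 20, "lying": 40})
        out = sp.balance_classes(mat, seed=3)
        assert len(out) == 80
        assert all(n == 20 for n in out["label"].value_counts())

    def test_already_balanced_keeps_rows(self):
        mat = toy_matrix({c: 25 for c in sp.MERGED_LABELS})
        out = sp.balance_classes(mat, seed=3)
        assert len(out) == 100
        a = mat.sort_values(list(mat.columns[:3])).reset_index(drop=True)
        b = out.sort_values(list(out.columns[:3])).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_deterministic_under_seed(self):
        mat = toy_matrix({"sitting": 50, "standing": 30, "stepping": 20, "lying": 40})
        out1 = sp.balance_classes(mat, seed=7)
        out2 = sp.balance_classes(mat, seed=7)
        pd.testing.assert_frame_equal(out1, out2)

    def test_absent_class_listed_in_error(self):
        mat = toy_matrix({"sitting": 5, "standing": 5, "stepping": 5})
        with pytest.raises(ValidationError, match="lying"):
            sp.balance_classes(mat, seed=0)


class TestTune:
    def test_single_point_grid_returned(self):
        mat = toy_matrix(BALANCED_200)
        spec = sp.tune(mat, "LDA", grid=[{}], seed=1)
        assert spec.family == "LDA" and spec.hyperparameters == {}

    def test_strong_spec_beats_degenerate_on_separable_data(self):
        mat = toy_matrix(BALANCED_200, sep=3.0)
        grid = [{"n_estimators": 1, "max_depth": 1}, {"n_estimators": 100}]
        spec = sp.tune(mat, "RF", grid=grid, seed=1)
        assert spec.hyperparameters == {"n_estimators": 100}

    def test_deterministic_under_seed(self):
        mat = toy_matrix(BALANCED_200)
        s1 = sp.tune(mat, "KNN", seed=4)
        s2 = sp.tune(mat, "KNN", seed=4)
        assert s1 == s2

    def test_too_small_subset_advises_larger_fraction(self):
        mat = toy_matrix({c: 12 for c in sp.MERGED_LABELS})
        with pytest.raises(ValidationError, match="fraction"):
            sp.tune(mat, "LDA", seed=0, tuning_fraction=0.10)


class TestCrossValidate:
    def test_separable_classes_give_perfect_scores(self):
        mat = toy_matrix({c: 60 for c in sp.MERGED_LABELS}, sep=8.0)
        spec = sp.ModelSpec("RF", {"n_estimators": 50}, random_seed=2)
        rep = sp.cross_validate(mat, spec, k=10, seed=2)
        assert rep.weighted_f == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(rep.confusion_matrix.to_numpy()), 100.0)

    def test_shuffled_labels_score_at_chance(self):
        rng = np.random.default_rng(0)
        mat = toy_matrix({c: 150 for c in sp.MERGED_LABELS}, sep=6.0)
        mat["label"] = rng.permutation(mat["label"].to_numpy())
        spec = sp.ModelSpec("RF", {"n_estimators": 50}, random_seed=0)
        rep = sp.cross_validate(mat, spec, k=10, seed=0)
        assert rep.weighted_f == pytest.approx(0.25, abs=0.06)

    def test_fold_stratification_matches_global_proportions(self):
        mat = toy_matrix({"sitting": 100, "standing": 50, "stepping": 50,
                          "lying": 100})
        from sklearn.model_selection import StratifiedKFold

        y = mat["label"].to_numpy()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=1)
        for _, te in skf.split(mat, y):
            counts = pd.Series(y[te]).value_counts()
            assert abs(counts["sitting"] - 10) <= 1
            assert abs(counts["stepping"] - 5) <= 1

    def test_recall_equals_confusion_diagonal(self):
        mat = toy_matrix({c: 60 for c in sp.MERGED_LABELS}, sep=1.5, seed=5)
        spec = sp.ModelSpec("LDA", random_seed=0)
        rep = sp.cross_validate(mat, spec, k=5, seed=3)
        for i, c in enumerate(sp.MERGED_LABELS):
            diag = rep.confusion_matrix.iloc[i, i] / 100.0
            assert rep.per_class_recall[c] == pytest.approx(diag, abs=0.02)

    def test_weighted_f_consistent_with_parts(self):
        mat = toy_matrix({c: 60 for c in sp.MERGED_LABELS}, sep=1.0, seed=8)
        rep = sp.cross_validate(mat, sp.ModelSpec("NB"), k=5, seed=1)
        manual = sum(
            rep.supports[c] / rep.n_samples * rep.per_class_f[c]
            for c in sp.MERGED_LABELS
        )
        assert rep.weighted_f == pytest.approx(manual, abs=1e-9)
        np.testing.assert_allclose(
            rep.confusion_matrix.to_numpy().sum(axis=1), 100.0, atol=0.01
        )

    def test_class_smaller_than_k_rejected(self):
        mat = toy_matrix({"sitting": 5, "standing": 20, "stepping": 20, "lying": 20})
        with pytest.raises(ValidationError, match="sitting"):
            sp.cross_validate(mat, sp.ModelSpec("NB"), k=10)


class TestEstimators:
    @pytest.mark.parametrize("family", sp.FAMILIES)
    def test_every_family_fits_and_predicts(self, family):
        mat = toy_matrix({c: 40 for c in sp.MERGED_LABELS}, sep=6.0)
        spec = sp.ModelSpec(family, DEFAULT_GRIDS[family][0], random_seed=0)
        est = sp.build_estimator(spec)
        X = mat[[c for c in mat.columns if c != "label"]].to_numpy()
        est.fit(X, mat["label"])
        acc = (est.predict(X) == mat["label"]).mean()
        assert acc > 0.9

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError, match="MLP"):
            sp.ModelSpec("MLP")


class TestRunExperiment:
    def test_reports_cover_the_cartesian_product(self, small_benchmark):
        datasets = sp.benchmark_datasets(small_benchmark, [15.0, 30.0])
        config = sp.ExperimentConfig(
            window_lengths=(15.0, 30.0), families=("RF", "NB"), k_folds=5,
            tuning_fraction=0.3, master_seed=1,
        )
        reports = sp.run_experiment(datasets, config=config)
        assert len(reports) == 4
        assert {(r.window_length, r.spec.family) for r in reports} == {
            (15.0, "RF"), (15.0, "NB"), (30.0, "RF"), (30.0, "NB")
        }
        table = sp.f_table(reports)
        assert table.shape == (2, 2)
        per_class = sp.per_class_table(reports, 15.0)
        assert set(per_class.columns) == set(sp.MERGED_LABELS) | {"weighted_f"}

    def test_unknown_family_in_config_rejected(self):
        with pytest.raises(ValidationError, match="allowed"):
            sp.ExperimentConfig(families=("RF", "CNN"))

    def test_stage_errors_carry_context(self, small_benchmark):
        datasets = sp.benchmark_datasets(small_benchmark, [15.0])
        config = sp.ExperimentConfig(
            window_lengths=(15.0,), families=("RF",), k_folds=10**6,
            master_seed=0,
        )
        with pytest.raises(ValidationError, match=r"window length 15.*RF"):
            sp.run_experiment(datasets, config=config)

    def test_leakage_safe_mode_runs_and_reports_selection(self, small_benchmark):
        datasets = sp.benchmark_datasets(small_benchmark, [30.0])
        config = sp.ExperimentConfig(
            window_lengths=(30.0,), families=("NB",), k_folds=5,
            tuning_fraction=0.3, master_seed=2, leakage_safe=True,
        )
        [rep] = sp.run_experiment(datasets, config=config)
        assert rep.selection is not None
        assert 0.0 <= rep.weighted_f <= 1.0


class TestSeedDerivation:
    def test_stage_seeds_distinct_and_reproducible(self):
        s1 = stage_seed(42, 0, 0, 0)
        s2 = stage_seed(42, 0, 0, 1)
        s3 = stage_seed(42, 0, 0, 0)
        assert s1 == s3 != s2
        assert 0 <= s1 < 2**31
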