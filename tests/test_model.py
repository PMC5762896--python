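"""BW-ratio ranking, LOOCV sweep, classification metrics, report bundle."""

import json

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from bcsradiomics.errors import ValidationError
from bcsradiomics.model import (
    SvmConfig,
    bw_ratio,
    consensus_features,
    loocv_sweep,
    metrics,
    rank_features,
    write_report,
)

from _oracles import brute_force_bw


def _toy_table(n=20, n_features=6, shift=5.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)].astype(int)
    X = rng.normal(size=(n, n_features))
    X[:, 0] += y * shift
    X[:, 1] += y * shift / 2
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df["label"] = y
    return df


class TestBwRatio:
    def test_hand_computed_value(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert bw_ratio(X, y)[0] == pytest.approx(3.375, abs=1e-12)

    def test_perfect_separator_ranked_first(self):
        y = np.array([0, 0, 1, 1])
        X = np.column_stack([np.random.default_rng(0).normal(size=4), y.astype(float)])
        bw = bw_ratio(X, y)
        assert np.isinf(bw[1])
        assert rank_features(X, y, ["noise", "copy"])[0] == 1

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            X = rng.normal(size=(n, int(rng.integers(2, 10))))
            y = rng.integers(0, 2, n)
            y[:2] = [0, 0]
            y[2:4] = [1, 1]
            np.testing.assert_allclose(bw_ratio(X, y), brute_force_bw(X, y), atol=1e-10)

    def test_shifted_feature_beats_noise(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.r_[np.zeros(10), np.ones(10)].astype(int)
            X = np.column_stack([rng.normal(size=20), rng.normal(size=20) + 3 * y])
            wins += rank_features(X, y, ["noise", "shifted"])[0] == 1
        assert wins >= 95

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            bw_ratio(np.ones((4, 2)), np.zeros(4, dtype=int))


class TestMetrics:
    def test_all_correct(self):
        y = np.array([0, 1, 0, 1])
        m = metrics(y, y)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (1.0, 1.0, 1.0)

    def test_always_negative_classifier(self):
        y = np.array([0, 0, 1, 1])
        m = metrics(y, np.zeros(4, dtype=int))
        assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0 and m["accuracy"] == 0.5

    def test_confusion_ratios(self):
        # TP=30 FN=12 TN=49 FP=18 -> 30/42 and 49/67
        y = np.r_[np.ones(42), np.zeros(67)].astype(int)
        pred = np.r_[np.ones(30), np.zeros(12), np.zeros(49), np.ones(18)].astype(int)
        m = metrics(y, pred)
        assert m["sensitivity"] * 100 == pytest.approx(71.4, abs=0.05)
        assert m["specificity"] * 100 == pytest.approx(73.1, abs=0.05)

    def test_clopper_pearson_brackets_point(self):
        y = np.r_[np.ones(42), np.zeros(67)].astype(int)
        pred = np.r_[np.ones(30), np.zeros(12), np.zeros(49), np.ones(18)].astype(int)
        m = metrics(y, pred)
        for stat in ("accuracy", "sensitivity", "specificity"):
            assert m[f"{stat}_ci_low"] < m[stat] < m[f"{stat}_ci_high"]
            assert 0.0 <= m[f"{stat}_ci_low"] and m[f"{stat}_ci_high"] <= 1.0

    def test_absent_class_is_nan(self):
        m = metrics(np.zeros(5, dtype=int), np.zeros(5, dtype=int))
        assert np.isnan(m["sensitivity"])


class TestLoocvSweep:
    def test_separable_classes_perfect_at_small_k(self):
        cv = loocv_sweep(_toy_table(shift=5.0), SvmConfig(max_k=5))
        small_k = cv.curve.loc[1:3]
        assert (small_k["sensitivity"] == 1.0).any()
        assert (small_k["specificity"] == 1.0).any()
        assert (small_k["accuracy"] == 1.0).any()

    def test_no_leakage_rankings_recomputable(self):
        table = _toy_table(shift=1.0, seed=3)
        cv = loocv_sweep(table, SvmConfig(max_k=3))
        X = table.drop(columns="label").to_numpy()
        y = table["label"].to_numpy()
        names = [c for c in table.columns if c != "label"]
        for i in range(len(table)):
            train = np.arange(len(table)) != i
            Xtr = X[train]
            mu, sd = Xtr.mean(0), Xtr.std(0)
            sd[sd == 0] = 1.0
            expected = rank_features((Xtr - mu) / sd, y[train], names)
            assert cv.fold_rankings[i].tolist() == expected

    def test_deterministic(self):
        a = loocv_sweep(_toy_table(seed=5), SvmConfig(max_k=4))
        b = loocv_sweep(_toy_table(seed=5), SvmConfig(max_k=4))
        np.testing.assert_array_equal(a.predictions, b.predictions)
        pd.testing.assert_frame_equal(a.curve, b.curve)

    def test_full_k_equals_plain_svm(self):
        """With k = n_features, selection is vacuous: predictions must match
        an SVM trained on all (standardized) features."""
        table = _toy_table(n=12, n_features=4, shift=1.5, seed=7)
        config = SvmConfig(max_k=4)
        cv = loocv_sweep(table, config)
        X = table.drop(columns="label").to_numpy()
        y = table["label"].to_numpy()
        for i in range(len(table)):
            train = np.arange(len(table)) != i
            Xtr = X[train]
            mu, sd = Xtr.mean(0), Xtr.std(0)
            sd[sd == 0] = 1.0
            clf = SVC(kernel="rbf", C=config.C, gamma=config.gamma)
            clf.fit((Xtr - mu) / sd, y[train])
            expected = clf.predict(((X[i] - mu) / sd).reshape(1, -1))[0]
            assert cv.predictions[i, 3] == expected

    def test_each_lesion_predicted_once_per_k(self):
        cv = loocv_sweep(_toy_table(), SvmConfig(max_k=6))
        assert cv.predictions.shape == (20, 6)
        assert set(np.unique(cv.predictions)) <= {0, 1}

    def test_too_small_input_rejected(self):
        df = _toy_table(n=3)
        with pytest.raises(ValidationError):
            loocv_sweep(df)


class TestReport:
    def test_bundle_files_and_reproducibility(self, tmp_path):
        table = _toy_table(seed=2)
        cv = loocv_sweep(table, SvmConfig(max_k=6))
        univ = pd.DataFrame({"feature": ["f0"], "rs": [0.5]})
        out1, out2 = tmp_path / "a", tmp_path / "b"
        write_report(cv, univ, out1)
        write_report(cv, univ, out2)
        for name in ("cv_curve.csv", "selected_features.csv", "univariate.csv",
                     "run_manifest.json"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
        curve = pd.read_csv(out1 / "cv_curve.csv")
        assert len(curve) == 6  # one row per k
        manifest = json.loads((out1 / "run_manifest.json").read_text())
        assert manifest["best_k"] == cv.best_k

    def test_consensus_list_structure(self):
        cv = loocv_sweep(_toy_table(seed=8), SvmConfig(max_k=4))
        cons = consensus_features(cv, k=3)
        assert list(cons["consensus_rank"]) == [1, 2, 3]
        assert set(cons.columns) >= {"feature", "scan", "mean_rank", "consensus_rank"}
        # strongly shifted features dominate the consensus
        assert "f0" in set(cons["feature"])

    def test_best_k_is_smallest_argmax(self):
        cv = loocv_sweep(_toy_table(shift=5.0), SvmConfig(max_k=6))
        best_acc = cv.curve["accuracy"].max()
        ks = cv.curve.index[cv.curve["accuracy"] == best_acc]
        assert cv.best_k == ks.min()
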