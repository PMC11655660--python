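"""Decoding machinery: pseudo-trial bookkeeping, leak-free
standardization/PCA, AUC calibration against closed-form oracles, and
cross-subtask transfer."""

import numpy as np
import pytest
from scipy import stats

from specdecode import DecodeConfig
from specdecode.decode import (
    decode_cross,
    decode_within,
    generalization_matrix,
    make_pseudotrials,
    standardize,
)


class TestMakePseudotrials:
    def test_remainder_trials_dropped(self):
        # 38 trials in one class with groups of 4 -> 9 pseudo-trials
        X = np.arange(38 * 2, dtype=float).reshape(38, 2)
        Xp, yp = make_pseudotrials(X, np.repeat("hard", 38), 4, 0)
        assert Xp.shape == (9, 2)
        assert len(yp) == 9

    def test_class_counts_equalized(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((38 + 30, 3))
        y = np.array(["a"] * 38 + ["b"] * 30)  # 9 vs 7 pseudo-trials
        Xp, yp = make_pseudotrials(X, y, 4, 1)
        assert (yp == "a").sum() == (yp == "b").sum() == 7

    def test_identical_trials_average_to_common_row(self):
        X = np.tile([2.0, -1.0, 0.5], (4, 1))
        Xp, yp = make_pseudotrials(X, np.repeat("a", 4), 4, 0)
        np.testing.assert_allclose(Xp, [[2.0, -1.0, 0.5]])

    def test_class_smaller_than_group_size_raises(self):
        with pytest.raises(ValueError, match="fewer"):
            make_pseudotrials(np.zeros((5, 2)), np.array(["a"] * 3 + ["b"] * 2), 4, 0)


class TestStandardize:
    def test_train_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        out = standardize(rng.standard_normal((20, 5)) * 3 + 2)
        np.testing.assert_allclose(out.train.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.train.std(axis=0), 1.0, atol=1e-10)

    def test_test_copy_of_train_matches(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 4))
        out = standardize(X, X.copy())
        np.testing.assert_allclose(out.test, out.train)

    def test_constant_column_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 3))
        X[:, 1] = 7.0
        with caplog.at_level("WARNING"):
            out = standardize(X, feature_names=["a", "b", "c"])
        assert out.train.shape == (10, 2)
        assert "b" in caplog.text

    def test_statistics_come_from_train_only(self):
        """Changing the test matrix never changes the fitted statistics —
        the no-leakage contract."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((12, 3))
        a = standardize(X, rng.standard_normal((5, 3)))
        b = standardize(X, 100.0 + rng.standard_normal((5, 3)))
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            standardize(np.zeros((1, 3)))


class TestDecodeWithin:
    def test_perfect_separation(self, gaussian_features):
        X, y = gaussian_features(n_per_class=40, effect=10.0, informative=0, seed=0)
        res = decode_within(X, y, DecodeConfig(n_reps=2, seed=0))
        assert res.auc == 1.0

    def test_gaussian_effect_matches_closed_form(self):
        """One informative feature with standardized mean difference d=1:
        AUC must approach the Gaussian oracle Phi(d/sqrt(2)) ~ 0.760."""
        rng = np.random.default_rng(5)
        n = 1000
        X = rng.standard_normal((2 * n, 1))
        X[n:] += 1.0
        y = np.repeat(["easy", "hard"], n)
        cfg = DecodeConfig(n_reps=2, pseudo_size=1, seed=1)
        res = decode_within(X, y, cfg)
        assert res.auc == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)), abs=0.02)

    def test_shuffled_labels_give_chance(self, gaussian_features):
        rng = np.random.default_rng(6)
        aucs = []
        for s in range(12):
            X, y = gaussian_features(n_per_class=20, effect=2.0, informative=0, seed=s)
            y = rng.permutation(y)
            aucs.append(decode_within(X, y, DecodeConfig(n_reps=3, seed=s)).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_deterministic_given_seed(self, gaussian_features):
        X, y = gaussian_features(effect=0.5, seed=7)
        a = decode_within(X, y, DecodeConfig(n_reps=3, seed=3)).auc
        b = decode_within(X, y, DecodeConfig(n_reps=3, seed=3)).auc
        c = decode_within(X, y, DecodeConfig(n_reps=3, seed=4)).auc
        assert a == b
        assert a != c

    def test_auc_monotone_in_effect_size(self, gaussian_features):
        """AUC must increase with the simulated effect over a 4-point
        grid (Spearman rho = 1)."""
        grid = (0.0, 0.5, 1.0, 1.5)
        aucs = []
        for effect in grid:
            X, y = gaussian_features(n_per_class=100, n_features=4, effect=effect,
                                     informative=0, seed=8)
            aucs.append(decode_within(X, y, DecodeConfig(n_reps=5, seed=8)).auc)
        assert stats.spearmanr(aucs, grid).statistic == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            decode_within(np.zeros((10, 2)), np.repeat("a", 10), DecodeConfig())


class TestDecodeCross:
    def test_negated_effect_map_anti_generalizes(self, gaussian_features):
        X_tr, y_tr = gaussian_features(n_per_class=60, n_features=6, effect=1.5,
                                       informative=slice(0, 3), seed=9)
        X_te, y_te = gaussian_features(n_per_class=60, n_features=6, seed=10)
        X_te[60:, :3] -= 1.5  # effect reversed in the test subtask
        auc = decode_cross(X_tr, y_tr, X_te, y_te, DecodeConfig(n_reps=5, seed=2))
        assert auc < 0.5

    def test_shuffled_test_labels_give_chance(self, gaussian_features):
        X_tr, y_tr = gaussian_features(n_per_class=60, effect=2.0, seed=11)
        X_te, _ = gaussian_features(n_per_class=60, seed=12)
        y_te = np.repeat(["easy", "hard"], 60)
        auc = decode_cross(X_tr, y_tr, X_te, y_te, DecodeConfig(n_reps=10, seed=3))
        assert auc == pytest.approx(0.5, abs=0.07)

    def test_matched_distribution_matches_within(self, gaussian_features):
        X_a, y_a = gaussian_features(n_per_class=80, effect=2.5, informative=0, seed=13)
        X_b, y_b = gaussian_features(n_per_class=80, effect=2.5, informative=0, seed=14)
        cfg = DecodeConfig(n_reps=5, seed=4)
        within = decode_within(X_a, y_a, cfg).auc
        cross = decode_cross(X_a, y_a, X_b, y_b, cfg)
        assert cross == pytest.approx(within, abs=0.05)

    def test_mismatched_features_rejected(self, gaussian_features):
        from specdecode.containers import SignalFeatures
        import pandas as pd

        X, y = gaussian_features(n_per_class=10, n_features=2, seed=0)
        labels = pd.DataFrame({
            "subject": "S00", "task": "WM", "content": "alphanumeric",
            "demand": y, "trial": range(len(y)),
        })
        a = SignalFeatures("alpha", X, ["c1", "c2"], labels)
        b = SignalFeatures("alpha", X, ["c1", "c3"], labels)
        with pytest.raises(ValueError, match="feature_ids"):
            decode_cross(a, y, b, y, DecodeConfig())


class TestGeneralizationMatrix:
    def test_symmetric_by_construction(self, gaussian_features):
        subtasks = {}
        for i, name in enumerate(["WM/num", "SWIT/num", "MSIT/num"]):
            X, y = gaussian_features(n_per_class=40, effect=1.0, seed=20 + i)
            subtasks[name] = (X, y)
        mat = generalization_matrix(subtasks, DecodeConfig(n_reps=2, seed=5))
        np.testing.assert_array_equal(mat.to_numpy(), mat.to_numpy().T)
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()

    def test_order_independence(self, gaussian_features):
        pairs = {n: gaussian_features(n_per_class=24, effect=1.0, seed=30 + i)
                 for i, n in enumerate(["a", "b"])}
        cfg = DecodeConfig(n_reps=2, seed=6)
        fwd = generalization_matrix(pairs, cfg)
        rev = generalization_matrix(dict(reversed(pairs.items())), cfg)
        np.testing.assert_allclose(fwd.loc["a", "b"], rev.loc["a", "b"])

    def test_needs_two_subtasks(self, gaussian_features):
        with pytest.raises(ValueError):
            generalization_matrix({"only": gaussian_features()}, DecodeConfig())
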