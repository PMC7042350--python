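"""k-fold cross-validation, skill metrics, OLS and MLP baselines."""

import logging

import numpy as np
import pandas as pd
import pytest

from gyretrend.evaluation import (
    MLPConfig, cross_validate, kfold_split, mlp_train, ols_fit, pearson_r,
    relative_mae,
)


class TestKFoldSplit:
    def test_even_split(self):
        groups = kfold_split(20, 10, seed=0)
        assert len(groups) == 10
        assert all(g.size == 2 for g in groups)
        assert np.array_equal(np.sort(np.concatenate(groups)), np.arange(20))

    def test_uneven_split_sizes(self):
        groups = kfold_split(23, 10, seed=1)
        sizes = sorted(g.size for g in groups)
        assert sizes == [2] * 7 + [3] * 3

    def test_deterministic(self):
        a = kfold_split(50, 10, seed=5)
        b = kfold_split(50, 10, seed=5)
        for ga, gb in zip(a, b):
            np.testing.assert_array_equal(ga, gb)

    @pytest.mark.parametrize("n,k", [(20, 10), (23, 10), (40, 4), (101, 7)])
    def test_disjoint_balanced_covering(self, n, k):
        groups = kfold_split(n, k, seed=2)
        sizes = [g.size for g in groups]
        assert max(sizes) - min(sizes) <= 1
        assert np.array_equal(np.sort(np.concatenate(groups)), np.arange(n))


class TestMetrics:
    def test_affine_prediction_perfect_correlation(self):
        obs = np.array([1.0, 2.0, 4.0, 7.0])
        assert pearson_r(2 * obs + 1, obs) == pytest.approx(1.0)

    def test_negated_prediction(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert pearson_r(-obs, obs) == pytest.approx(-1.0)

    def test_constant_prediction_errors(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(4), np.arange(4.0))

    def test_relative_mae_perfect(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert relative_mae(obs, obs) == 0.0

    def test_relative_mae_mean_predictor_is_100(self):
        obs = np.array([1.0, 5.0, 3.0, 7.0])
        assert relative_mae(np.full(4, obs.mean()), obs) == pytest.approx(100.0)

    def test_relative_mae_above_100(self):
        assert relative_mae(np.array([2.0, 0.0]),
                            np.array([0.0, 2.0])) == pytest.approx(200.0)

    def test_relative_mae_constant_observations_error(self):
        with pytest.raises(ValueError):
            relative_mae(np.arange(3.0), np.ones(3))

    def test_relative_mae_scale_invariant(self):
        obs = np.array([1.0, 5.0, 3.0])
        pred = np.array([2.0, 4.0, 3.5])
        assert relative_mae(10 * pred, 10 * obs) == pytest.approx(
            relative_mae(pred, obs))


class _PerfectTrainer:
    """Returns the (noise-free) generating law."""

    def __call__(self, table):
        return self

    text = "oracle"

    def predict(self, table):
        return 400.0 - 30.0 * (table["temp"] - 21.0) + 4.0 * table["fuco"]


class _MeanTrainer:
    def __call__(self, table):
        m = float(table["npp"].mean())

        class Model:
            text = f"mean={m:.3f}"

            def predict(self, t, _m=m):
                return np.full(len(t), _m)
        return Model()


class _LeakProbe:
    """Records every set of row ids it was trained on."""

    def __init__(self):
        self.train_sets = []

    def __call__(self, table):
        self.train_sets.append(set(table.index))
        return _MeanTrainer()(table)


class TestCrossValidate:
    def test_perfect_trainer(self, feature_frame):
        df = feature_frame.copy()
        df["npp"] = 400.0 - 30.0 * (df["temp"] - 21.0) + 4.0 * df["fuco"]
        report = cross_validate(_PerfectTrainer(), df, k=10, seed=0)
        assert report.pooled_r == pytest.approx(1.0)
        assert report.pooled_error_pct == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_trainer_scores_about_100(self, feature_frame, seed):
        report = cross_validate(_MeanTrainer(), feature_frame, k=10, seed=seed)
        # slightly above 100 because each fold predicts its own training mean
        assert 95.0 < report.pooled_error_pct < 130.0
        assert report.pooled_error_pct > 100.0

    def test_leave_one_out_boundary(self, feature_frame):
        n = len(feature_frame)
        report = cross_validate(_MeanTrainer(), feature_frame, k=n, seed=0)
        assert len(report.folds) == n
        assert all(f.test_ids.size == 1 for f in report.folds)

    def test_no_test_rows_in_training(self, feature_frame):
        probe = _LeakProbe()
        report = cross_validate(probe, feature_frame, k=6, seed=3)
        for fold, train_set in zip(report.folds, probe.train_sets):
            assert train_set.isdisjoint(set(fold.test_ids))
            assert train_set | set(fold.test_ids) == set(range(len(feature_frame)))

    def test_failing_folds_reported_then_fatal(self, feature_frame):
        calls = {"n": 0}

        def flaky(table):
            calls["n"] += 1
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="folds failed"):
            cross_validate(flaky, feature_frame, k=5, seed=0)

    def test_too_few_rows_rejected(self, feature_frame):
        with pytest.raises(ValueError, match="2k"):
            cross_validate(_MeanTrainer(), feature_frame.head(10), k=8, seed=0)


class TestOLS:
    def test_recovers_noise_free_law(self, feature_frame):
        df = feature_frame.copy()
        df["npp"] = 400.0 - 30.0 * (df["temp"] - 21.0) + 4.0 * df["fuco"]
        m = ols_fit(df)
        assert m.coefficients["temp"] == pytest.approx(-30.0, rel=1e-6)
        assert m.coefficients["fuco"] == pytest.approx(4.0, rel=1e-6)
        assert abs(m.coefficients["po4"]) < 1e-6

    def test_two_points_exact_line(self):
        df = pd.DataFrame({"temp": [1.0, 3.0], "npp": [5.0, 9.0]})
        m = ols_fit(df, predictors=["temp"])
        assert m.intercept == pytest.approx(3.0)
        assert m.coefficients["temp"] == pytest.approx(2.0)

    def test_duplicated_predictor_ridge_fallback(self, feature_frame, caplog):
        df = feature_frame.copy()
        df["temp2"] = df["temp"]
        with caplog.at_level(logging.WARNING):
            m = ols_fit(df, predictors=["temp", "temp2"])
        assert m.ridge_fallback
        assert any("ridge" in r.message for r in caplog.records)
        pred = m.predict(df)
        assert np.all(np.isfinite(pred))


class TestMLP:
    def test_single_predictor_regression(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-2, 2, 200)
        df = pd.DataFrame({"temp": x, "npp": 3.0 * x + 1.0})
        m = mlp_train(df, MLPConfig(max_epochs=3000, learning_rate=0.05,
                                    seed=0),
                      predictors=["temp"])
        pred = m.predict(df)
        assert pearson_r(pred, df["npp"].to_numpy()) > 0.99

    def test_zero_epochs_is_random_init(self, feature_frame):
        m = mlp_train(feature_frame, MLPConfig(max_epochs=0, seed=1))
        assert m.epochs_trained == 0
        # random init: essentially no skill relative to the mean predictor
        err = relative_mae(m.predict(feature_frame),
                           feature_frame["npp"].to_numpy())
        assert err > 60.0

    def test_deterministic_given_seed(self, feature_frame):
        cfg = MLPConfig(max_epochs=100, seed=3)
        a = mlp_train(feature_frame, cfg)
        b = mlp_train(feature_frame, cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_divergence_raises_with_advice(self, feature_frame):
        with pytest.raises(FloatingPointError, match="learning_rate"):
            mlp_train(feature_frame, MLPConfig(max_epochs=2000,
                                               learning_rate=1e4, seed=0))

    def test_early_stopping_engages(self, feature_frame):
        m = mlp_train(feature_frame, MLPConfig(max_epochs=5000, patience=10,
                                               seed=0))
        assert m.epochs_trained < 5000

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MLPConfig(learning_rate=0.0).validate()
        with pytest.raises(ValueError):
            MLPConfig(hidden_layers=()).validate()
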