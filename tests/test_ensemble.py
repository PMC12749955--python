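"""Bootstrap ensemble training, prediction and evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from sdproxy import (
    EnsembleConfig,
    binned_errors,
    ensemble_metrics,
    evaluate,
    load_ensemble,
    predict,
    save_ensemble,
    split_train_validation,
    train_ensemble,
)


class TestSplit:
    def test_seventy_thirty_sizes(self):
        t = pd.DataFrame({"x": range(10)})
        tr, va = split_train_validation(t, 0.7, seed=1)
        assert len(tr) == 7 and len(va) == 3

    def test_disjoint_and_exhaustive(self):
        t = pd.DataFrame({"x": range(101)})
        tr, va = split_train_validation(t, 0.7, seed=5)
        assert set(tr) | set(va) == set(range(101))
        assert set(tr) & set(va) == set()

    def test_same_seed_same_split(self):
        t = pd.DataFrame({"x": range(50)})
        a = split_train_validation(t, 0.7, seed=9)
        b = split_train_validation(t, 0.7, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            split_train_validation(pd.DataFrame({"x": [1]}), 1.5, 0)


class TestTrainPredict:
    def test_bootstrap_rows_stay_inside_training_split(self, tiny_ensemble):
        train = set(tiny_ensemble.train_ids)
        val = set(tiny_ensemble.validation_ids)
        for idx in tiny_ensemble.bootstrap_indices:
            assert set(idx) <= train
            assert not set(idx) & val

    def test_single_member_mean_equals_member(self, small_sdp_table):
        ens = train_ensemble(small_sdp_table, EnsembleConfig(n_models=1, n_trees=10, seed=2))
        members, mean = predict(ens, small_sdp_table)
        np.testing.assert_array_equal(members[:, 0], mean)

    def test_constant_response_predicts_the_constant(self, small_sdp_table):
        t = small_sdp_table.copy()
        t["sdp"] = 0.42
        with pytest.warns(UserWarning, match="constant"):
            ens = train_ensemble(t, EnsembleConfig(n_models=2, n_trees=5, seed=0))
        _, mean = predict(ens, t)
        np.testing.assert_allclose(mean, 0.42, atol=1e-12)

    def test_deterministic_given_seed(self, small_sdp_table):
        cfg = EnsembleConfig(n_models=2, n_trees=10, seed=4)
        a = train_ensemble(small_sdp_table, cfg)
        b = train_ensemble(small_sdp_table, cfg)
        np.testing.assert_array_equal(
            a.predict_members(small_sdp_table), b.predict_members(small_sdp_table)
        )

    def test_predictions_clipped_to_unit_interval(self, tiny_ensemble, small_sdp_table):
        members, mean = predict(tiny_ensemble, small_sdp_table)
        assert members.min() >= 0.0 and members.max() <= 1.0
        assert mean.min() >= 0.0 and mean.max() <= 1.0

    def test_missing_predictor_is_schema_error(self, small_sdp_table):
        with pytest.raises(KeyError, match="DEM"):
            train_ensemble(small_sdp_table.drop(columns=["DEM"]), EnsembleConfig(n_models=1))

    def test_unseen_categorical_maps_to_fallback(self, tiny_ensemble, small_sdp_table):
        t = small_sdp_table.copy()
        t.loc[t.index[0], "landcover"] = "wetland"
        with pytest.warns(UserWarning, match="wetland"):
            tiny_ensemble.predict_members(t)

    def test_step_function_recovered_by_forest(self):
        """A noise-free single-predictor step response is reproduced at the
        training points within forest resolution."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 320)
        t = pd.DataFrame({"x": x, "sdp": np.where(x > 0.5, 0.8, 0.2)})
        cfg = EnsembleConfig(n_models=1, n_trees=50, seed=0, predictors=("x",), categorical=())
        ens = train_ensemble(t, cfg)
        _, mean = predict(ens, t)
        # forest resolution: the step location is only pinned to the data
        # spacing, so judge away from a small neighborhood of the jump
        away = np.abs(x - 0.5) > 0.02
        np.testing.assert_allclose(mean[away], t["sdp"][away], atol=0.05)

    def test_bundle_round_trip(self, tmp_path, tiny_ensemble, small_sdp_table):
        save_ensemble(tiny_ensemble, tmp_path / "ens")
        back = load_ensemble(tmp_path / "ens")
        np.testing.assert_array_equal(
            tiny_ensemble.predict_members(small_sdp_table),
            back.predict_members(small_sdp_table),
        )
        assert back.levels == tiny_ensemble.levels


class TestEvaluate:
    def test_perfect_predictions(self):
        m = evaluate([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert m == {"r_squared": 1.0, "rmse": 0.0, "mae": 0.0}

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([0.2, 0.4, 0.9])
        m = evaluate(np.full(3, obs.mean()), obs)
        assert m["r_squared"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic_fixture(self):
        m = evaluate([0.5, 0.5], [0.0, 1.0])
        assert m["mae"] == 0.5 and m["rmse"] == 0.5

    def test_agrees_with_sklearn_metrics(self, rng):
        obs = rng.uniform(size=50)
        pred = obs + rng.normal(0, 0.1, size=50)
        m = evaluate(pred, obs)
        assert m["r_squared"] == pytest.approx(r2_score(obs, pred), abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(mean_squared_error(obs, pred)), abs=1e-12)
        assert m["mae"] == pytest.approx(mean_absolute_error(obs, pred), abs=1e-12)

    def test_zero_variance_observations_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate([0.1, 0.2], [0.5, 0.5])


class TestBinnedErrors:
    def test_single_low_bin_populated(self):
        out = binned_errors([0.1, 0.2], [0.05, 0.05])
        assert out["count"].tolist() == [2] + [0] * 9

    def test_counts_sum_to_n(self, rng):
        obs = rng.uniform(size=77)
        out = binned_errors(obs, obs)
        assert out["count"].sum() == 77

    def test_top_edge_belongs_to_last_bin(self):
        out = binned_errors([1.0], [1.0])
        assert out["count"].iloc[-1] == 1

    def test_sparse_low_tail_has_larger_errors(self):
        """A forest trained where low response values are scarce makes larger
        errors in the low bins than in the well-sampled mid bins."""
        rng = np.random.default_rng(5)
        x_train = rng.uniform(0, 1, 600) ** 0.35  # density rises with x: sparse low tail
        train = pd.DataFrame({"x": x_train, "sdp": x_train})
        cfg = EnsembleConfig(n_models=1, n_trees=30, seed=0, predictors=("x",), categorical=())
        ens = train_ensemble(train, cfg)
        x_test = rng.uniform(0, 1, 800)
        test = pd.DataFrame({"x": x_test})
        _, mean = predict(ens, test)
        out = binned_errors(mean, x_test)
        low = out.loc[0, "mean_abs"]
        mid = out.loc[5, "mean_abs"]
        assert low > mid


def test_ensemble_metrics_report_shape(tiny_ensemble, small_sdp_table):
    rep = ensemble_metrics(tiny_ensemble, small_sdp_table)
    assert set(rep.per_member["split"]) == {"train", "validation"}
    assert len(rep.per_member) == 2 * tiny_ensemble.n_models
    assert (rep.per_member["rmse"] >= rep.per_member["mae"]).all()
    assert rep.binned["count"].sum() == len(tiny_ensemble.validation_ids)
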