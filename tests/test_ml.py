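"""Encoding, cross-validation discipline, and the three importance methods."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from broilerenv import ml


def make_raw(n=120, seed=0, noise=0.5):
    """Raw predictor table with one strong linear signal and a categorical."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(0, 10, n)
    x2 = rng.normal(0, 1, n)
    region = rng.choice(["East", "Midwest", "Northwest"], n)
    y = 3.0 * x1 + rng.normal(0, noise, n)
    return pd.DataFrame({"x1": x1, "x2": x2, "region": region, "y": y})


class TestEncodeAndScale:
    def test_dummy_coding_drops_reference_level(self):
        mm = ml.encode_and_scale(make_raw(), "y")
        region_cols = [c for c in mm.columns if c.startswith("region_")]
        assert len(region_cols) == 2  # 3 levels -> 2 indicators
        assert mm.reference_levels["region"] == "East"
        assert set(np.unique(mm.X[region_cols].to_numpy())) <= {0.0, 1.0}

    def test_minmax_scaling(self):
        raw = pd.DataFrame({"a": [2.0, 4.0, 6.0], "y": [1.0, 2.0, 3.0]})
        mm = ml.encode_and_scale(raw, "y")
        assert mm.X["a"].tolist() == [0.0, 0.5, 1.0]

    def test_every_column_spans_unit_interval(self):
        mm = ml.encode_and_scale(make_raw(), "y")
        assert np.allclose(mm.X.min(), 0.0)
        assert np.allclose(mm.X.max(), 1.0)

    def test_constant_column_dropped_with_warning(self):
        raw = make_raw(30)
        raw["const"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            mm = ml.encode_and_scale(raw, "y")
        assert "const" not in mm.columns

    def test_frozen_params_scale_held_out_below_zero(self):
        """Transforming a held-out value below the training minimum yields a
        negative scaled value - the scaler must not refit."""
        raw = pd.DataFrame({"a": [2.0, 4.0, 6.0], "y": [1.0, 2.0, 3.0]})
        mm = ml.encode_and_scale(raw, "y")
        out = mm.transform(pd.DataFrame({"a": [0.0]}))
        assert out.loc[0, "a"] == pytest.approx(-0.5)


class TestKfold:
    def test_even_split(self):
        labels = ml.kfold_split(100, 5, seed=0)
        assert sorted(np.bincount(labels)) == [20] * 5

    def test_uneven_split_sizes_differ_by_at_most_one(self):
        labels = ml.kfold_split(23, 5, seed=0)
        assert sorted(np.bincount(labels)) == [4, 4, 5, 5, 5]

    def test_deterministic_under_seed(self):
        assert (ml.kfold_split(40, 5, seed=3) == ml.kfold_split(40, 5, seed=3)).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ml.kfold_split(3, 5)


class TestEvaluate:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert ml.evaluate(y, y) == (pytest.approx(1.0), pytest.approx(0.0))
        r2, _ = ml.evaluate(np.full(4, y.mean()), y)
        assert r2 == pytest.approx(0.0)

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        p = t + rng.normal(0, 0.3, 50)
        r2, rmse = ml.evaluate(p, t)
        sse = ((t - p) ** 2).sum()
        sst = ((t - t.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - sse / sst, abs=1e-12)
        assert rmse == pytest.approx(np.sqrt(sse / 50), abs=1e-12)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            ml.evaluate([1.0, 2.0], [3.0, 3.0])


class TestMlr:
    def test_orthogonal_predictors_all_vif_one_none_dropped(self):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(40, 3)))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = X["a"] * 2 + X["b"] - X["c"] + rng.normal(0, 0.01, 40)
        model = ml.fit_mlr_selected(X, y, vif_max=10, alpha=0.05)
        assert model.dropped_vif == []
        assert set(model.columns) == {"a", "b", "c"}

    def test_duplicated_column_dropped_by_vif(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "dup": a, "b": rng.normal(size=50)})
        y = a * 2 + rng.normal(0, 0.1, 50)
        model = ml.fit_mlr_selected(X, y)
        assert len(model.dropped_vif) == 1
        assert model.dropped_vif[0] in {"a", "dup"}

    def test_pure_noise_predictor_usually_eliminated(self):
        """Type-I behaviour of backward elimination: a noise column survives
        at alpha=0.05 in roughly 5% of replicates."""
        rng = np.random.default_rng(2)
        kept = 0
        reps = 100
        for _ in range(reps):
            x = rng.uniform(0, 1, 60)
            noise_col = rng.normal(size=60)
            X = pd.DataFrame({"x": x, "noise": noise_col})
            y = 4 * x + rng.normal(0, 0.3, 60)
            model = ml.fit_mlr_selected(X, y, alpha=0.05)
            kept += "noise" in model.columns
        assert kept / reps < 0.15

    def test_contribution_single_predictor_is_100(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 30)})
        y = 2 * X["a"] + rng.normal(0, 0.1, 30)
        model = ml.fit_mlr_selected(X, y)
        imp = ml.mlr_contribution(model, X, y)
        assert imp.table.loc[0, "score"] == pytest.approx(100.0)

    def test_contribution_orthogonal_order_invariant(self):
        """For orthogonal predictors the partial SS equals each predictor's
        own SS share, independent of column order."""
        rng = np.random.default_rng(4)
        # orthogonalise against the intercept too, so partial SS adds exactly
        q, _ = np.linalg.qr(np.column_stack([np.ones(60), rng.normal(size=(60, 2))]))
        X = pd.DataFrame(q[:, 1:], columns=["a", "b"])
        y = 3 * X["a"] + 1.5 * X["b"] + rng.normal(0, 0.05, 60)
        model = ml.fit_mlr_selected(X, y)
        imp1 = ml.mlr_contribution(model, X, y).table.set_index("variable")["score"]
        Xr = X[["b", "a"]]
        model_r = ml.fit_mlr_selected(Xr, y)
        imp2 = ml.mlr_contribution(model_r, Xr, y).table.set_index("variable")["score"]
        assert imp1["a"] == pytest.approx(imp2["a"], rel=1e-9)
        assert imp1["a"] > imp1["b"]
        assert imp1.sum() == pytest.approx(100.0, abs=1.0)

    def test_cv_mean_r2_not_above_in_sample(self):
        raw = make_raw(80, seed=5, noise=2.0)
        cv = ml.cross_validate_mlr(raw, "y", k=5, seed=0)
        mm = ml.encode_and_scale(raw, "y")
        model = ml.fit_mlr_selected(mm.X, mm.y)
        assert cv.mean_r2 <= model.results.rsquared + 0.02

    def test_no_leakage_from_held_out_responses(self):
        """Scrambling the responses of one fold's rows must not change the
        predictions for that fold (preprocessing and fit are train-only)."""
        raw = make_raw(60, seed=6)
        folds = ml.kfold_split(len(raw), 5, seed=1)
        test_rows = folds == 0

        def fold0_predictions(table):
            train = table[~test_rows]
            mm = ml.encode_and_scale(train, "y")
            model = ml.fit_mlr_selected(mm.X, mm.y)
            return model.predict(mm.transform(table[test_rows].drop(columns=["y"])))

        base = fold0_predictions(raw)
        scrambled = raw.copy()
        scrambled.loc[test_rows, "y"] = 999.0
        assert np.allclose(base, fold0_predictions(scrambled))


@pytest.fixture(scope="module")
def signal_data():
    raw = make_raw(150, seed=7, noise=1.0)
    return ml.encode_and_scale(raw, "y")


class TestRandomForest:

    def test_oob_machinery_matches_sklearn(self, signal_data):
        """Reconstructed per-tree OOB sets reproduce sklearn's own
        oob_prediction_ exactly."""
        mm = signal_data
        rf = RandomForestRegressor(n_estimators=60, random_state=0,
                                   oob_score=True, bootstrap=True)
        rf.fit(mm.X, mm.y)
        sets = ml._oob_sets(rf, len(mm.X))
        pred = ml._oob_predict(rf, mm.X.to_numpy(float), sets)
        assert np.allclose(pred, rf.oob_prediction_, equal_nan=True)

    def test_strong_predictor_gives_positive_cv_r2(self, signal_data):
        model = ml.fit_rf(signal_data.X, signal_data.y, n_trees=100, seed=0)
        assert model.cv.mean_r2 > 0.5
        assert model.oob_mse < np.var(signal_data.y)

    def test_pure_noise_response_cv_r2_near_zero(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.uniform(size=(100, 3)), columns=list("abc"))
        y = rng.normal(size=100)
        model = ml.fit_rf(X, y, n_trees=100, seed=0)
        assert model.cv.mean_r2 < 0.15

    def test_same_seed_identical(self, signal_data):
        a = ml.fit_rf(signal_data.X, signal_data.y, n_trees=50, seed=4)
        b = ml.fit_rf(signal_data.X, signal_data.y, n_trees=50, seed=4)
        assert a.mtry == b.mtry
        assert a.cv.fold_rmse == b.cv.fold_rmse
        assert np.allclose(a.forest.predict(signal_data.X),
                           b.forest.predict(signal_data.X))

    def test_permutation_importance_ranks_signal_first(self, signal_data):
        model = ml.fit_rf(signal_data.X, signal_data.y, n_trees=100, seed=0)
        imp = ml.permutation_importance(model, signal_data.X, signal_data.y,
                                        n_reps=5, seed=0)
        assert imp.table.loc[0, "variable"] == "x1"
        assert imp.table.loc[0, "score"] > 10

    def test_irrelevant_feature_score_near_zero(self, signal_data):
        """Permuting a feature the forest never learned from leaves the OOB
        MSE essentially unchanged."""
        model = ml.fit_rf(signal_data.X, signal_data.y, n_trees=100, seed=0)
        imp = ml.permutation_importance(model, signal_data.X, signal_data.y,
                                        n_reps=10, seed=0).table.set_index("variable")
        assert abs(imp.loc["x2", "score"]) < 5.0


@pytest.fixture(scope="module")
def linear_data():
    raw = make_raw(120, seed=9, noise=0.3)[["x1", "x2", "y"]]
    return ml.encode_and_scale(raw, "y")


class TestAnn:

    def test_linear_response_approaches_ols_fit(self, linear_data):
        model = ml.fit_ann(linear_data.X, linear_data.y, nodes_grid=(1, 3),
                           decay=1e-4, seed=0)
        assert model.cv.mean_r2 > 0.9

    def test_same_seed_identical_weights(self, linear_data):
        a = ml.fit_ann(linear_data.X, linear_data.y, nodes_grid=(2,), seed=1)
        b = ml.fit_ann(linear_data.X, linear_data.y, nodes_grid=(2,), seed=1)
        for wa, wb in zip(a.net.coefs_, b.net.coefs_):
            assert np.array_equal(wa, wb)

    def test_rmse_in_response_units(self, linear_data):
        model = ml.fit_ann(linear_data.X, linear_data.y, nodes_grid=(3,), seed=0)
        spread = linear_data.y.max() - linear_data.y.min()
        assert 0 < model.cv.mean_rmse < spread


class TestOlden:
    def _net(self, w_ih, w_ho):
        net = ml.MLPRegressor(hidden_layer_sizes=(w_ih.shape[1],))
        net.coefs_ = [w_ih, w_ho]
        return net

    def test_single_hidden_node_product(self):
        net = self._net(np.array([[2.0]]), np.array([[3.0]]))
        imp = ml.olden_importance(net, ["a"])
        assert imp.table.loc[0, "score"] == pytest.approx(6.0)

    def test_zero_outgoing_weights_zero_importance(self):
        net = self._net(np.array([[0.0, 0.0], [1.0, 2.0]]), np.array([[3.0], [1.0]]))
        imp = ml.olden_importance(net, ["dead", "live"]).table.set_index("variable")
        assert imp.loc["dead", "score"] == 0.0

    def test_cancelling_products_sum_to_zero(self):
        """Hidden paths +4 and -4 cancel: the measure is signed."""
        net = self._net(np.array([[2.0, -2.0]]), np.array([[2.0], [2.0]]))
        imp = ml.olden_importance(net, ["a"])
        assert imp.table.loc[0, "score"] == pytest.approx(0.0)

    def test_linear_in_output_weights(self):
        rng = np.random.default_rng(0)
        w_ih = rng.normal(size=(4, 3))
        w_ho = rng.normal(size=(3, 1))
        base = ml.olden_importance(self._net(w_ih, w_ho)).table.set_index("variable")["score"]
        doubled = ml.olden_importance(self._net(w_ih, 2 * w_ho)).table.set_index("variable")["score"]
        assert np.allclose(doubled, 2 * base)

    def test_multi_layer_rejected(self):
        net = ml.MLPRegressor(hidden_layer_sizes=(3, 3))
        net.coefs_ = [np.ones((2, 3)), np.ones((3, 3)), np.ones((3, 1))]
        with pytest.raises(ValueError):
            ml.olden_importance(net)
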