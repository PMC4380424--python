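"""QSPR pipeline: target transform, split, selection, standardization, SVR."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVR

from metastab import qspr_model, synthetic_data
from metastab.qspr_model import (
    ModelConfig,
    QsprError,
    fit_qspr,
    optimize_hyperparams,
    predict,
    remove_constant,
    select_features,
    split,
    standardize_fit,
    train_svr,
    transform_target,
    validate,
)


class TestRemoveConstant:
    def test_constant_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 3, 3]})
        out = remove_constant(df)
        assert list(out.columns) == ["a"]

    def test_identity_when_no_constants(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [0.0, 1, 0]})
        pd.testing.assert_frame_equal(remove_constant(df), df)

    def test_counts(self):
        df = pd.DataFrame(
            {f"c{i}": ([1.0, 1, 1] if i < 4 else [1.0, 2, float(i)]) for i in range(10)}
        )
        assert remove_constant(df).shape[1] == 6

    def test_all_constant_is_error(self):
        with pytest.raises(QsprError):
            remove_constant(pd.DataFrame({"a": [1.0, 1], "b": [2.0, 2]}))


class TestTransformTarget:
    def test_log10(self):
        y, _ = transform_target(np.array([10.0, 100.0]))
        assert np.allclose(y, [1.0, 2.0])

    def test_unit_half_life_maps_to_zero(self):
        y, _ = transform_target(np.array([1.0, 1.0, 1.0]))
        assert np.allclose(y, 0.0)

    def test_panel_values_report_normality(self):
        t = [r.t_half_min for r in synthetic_data.load_table1()
             if r.compound_id != "buspirone"]
        y, rep = transform_target(np.array(t))
        assert len(y) == 30
        assert np.isfinite(rep.p_value) and 0 <= rep.p_value <= 1
        assert np.isfinite(rep.statistic)

    def test_nonpositive_rejected(self):
        with pytest.raises(QsprError):
            transform_target(np.array([5.0, 0.0]))


class TestSplit:
    def test_disjoint_and_complete(self):
        ids = [f"c{i}" for i in range(30)]
        tr, te = split(ids, 22, 8, seed=5)
        assert len(tr) == 22 and len(te) == 8
        assert set(tr) | set(te) == set(ids)
        assert set(tr) & set(te) == set()

    def test_deterministic_per_seed(self):
        ids = list(range(30))
        assert split(ids, 22, 8, seed=3) == split(ids, 22, 8, seed=3)

    def test_seed_variation(self):
        # C(30, 8) is ~5.9e6, so 10 different seeds collide with
        # negligible probability
        ids = list(range(30))
        tests = {tuple(split(ids, 22, 8, seed=s)[1]) for s in range(10)}
        assert len(tests) >= 9

    def test_size_mismatch_error(self):
        with pytest.raises(QsprError):
            split(list(range(30)), 25, 8, seed=0)


class TestSelectFeatures:
    def _table(self, rng, n=20):
        return pd.DataFrame(
            rng.standard_normal((n, 5)), columns=[f"d{i}" for i in range(1, 6)]
        )

    def test_exact_copy_ranked_first(self, rng):
        X = self._table(rng)
        y = X["d3"].to_numpy()
        assert select_features(X, y, k=1, method="pearson") == ["d3"]

    def test_negated_copy_ranked_first(self, rng):
        X = self._table(rng)
        y = -X["d2"].to_numpy()
        assert select_features(X, y, k=1, method="pearson") == ["d2"]

    def test_k_equals_columns_returns_all(self, rng):
        X = self._table(rng)
        y = rng.standard_normal(len(X))
        assert set(select_features(X, y, k=5, method="pearson")) == set(X.columns)

    def test_forward_cv_finds_signal(self, rng):
        X = self._table(rng)
        y = X["d1"].to_numpy() * 0.9
        picked = select_features(X, y, k=2, method="forward-cv")
        assert picked[0] == "d1"

    def test_zero_variance_column_excluded(self, rng):
        X = self._table(rng)
        X["dead"] = 1.0
        y = X["d1"].to_numpy()
        picked = select_features(X, y, k=5, method="pearson")
        assert "dead" not in picked


class TestStandardize:
    def test_training_stats(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z = standardize_fit(X).transform(X)
        assert np.allclose(z["a"], [-1.0, 0.0, 1.0])  # sample sd = 1

    def test_test_row_at_training_mean_maps_to_zero(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        std = standardize_fit(X)
        z = std.transform(pd.DataFrame({"a": [2.0]}))
        assert z["a"].iloc[0] == 0.0

    def test_shift_invariance(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(10)})
        z1 = standardize_fit(X).transform(X)
        Xs = X + 17.3
        z2 = standardize_fit(Xs).transform(Xs)
        assert np.allclose(z1, z2)

    def test_zero_sd_names_column(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(QsprError, match="flat"):
            standardize_fit(X)


class TestTrainPredict:
    def test_constant_response_predicts_constant(self, rng):
        Z = pd.DataFrame(rng.standard_normal((10, 2)), columns=["a", "b"])
        model = train_svr(Z, np.full(10, 0.5))
        assert model.warnings
        assert np.allclose(predict(model, Z), 0.5)

    def test_training_points_within_epsilon_tube(self, rng):
        # well-separated 1-D toy: non-support vectors sit inside the tube
        x = np.linspace(-2, 2, 10)[:, None]
        y = 0.3 * x.ravel()
        model = train_svr(x, y, {"C": 100.0, "epsilon": 0.1, "gamma": 0.5})
        resid = np.abs(model.svr.predict(x) - y)
        assert np.all(resid <= 0.1 + 1e-6)

    def test_sine_fit_against_reference_svr(self):
        x = np.linspace(0, 2 * np.pi, 20)[:, None]
        y = np.sin(x).ravel()
        params = {"C": 10.0, "epsilon": 0.1, "gamma": 0.9}
        model = train_svr(x, y, params)
        ours = model.svr.predict(x)
        ref = SVR(kernel="rbf", **{"C": 10.0, "epsilon": 0.1, "gamma": 0.9}).fit(x, y)
        assert np.allclose(ours, ref.predict(x), atol=1e-10)
        assert np.mean((ours - y) ** 2) < 0.01  # within epsilon^2

    def test_nonpositive_params_rejected(self, rng):
        Z = rng.standard_normal((5, 2))
        with pytest.raises(QsprError):
            train_svr(Z, rng.standard_normal(5), {"C": -1, "epsilon": 0.1, "gamma": 1})


class TestOptimizeHyperparams:
    def test_single_iteration_returns_sample(self, rng):
        Z = rng.standard_normal((12, 2))
        y = Z[:, 0]
        params = optimize_hyperparams(Z, y, n_iter=1, seed=4)
        assert set(params) == {"C", "epsilon", "gamma", "objective_value"}

    def test_deterministic_per_seed(self, rng):
        Z = rng.standard_normal((12, 2))
        y = Z[:, 0]
        a = optimize_hyperparams(Z, y, n_iter=10, seed=9)
        b = optimize_hyperparams(Z, y, n_iter=10, seed=9)
        assert a == b

    def test_argmin_property(self, rng):
        Z = rng.standard_normal((12, 2))
        y = Z[:, 0] + 0.05 * rng.standard_normal(12)
        best = optimize_hyperparams(Z, y, n_iter=15, seed=2, objective="train")
        # re-evaluate a fresh sample of candidates: none beats the argmin
        rng2 = np.random.default_rng(2)
        for _ in range(15):
            cand = {
                "C": float(np.exp(rng2.uniform(np.log(0.1), np.log(100)))),
                "epsilon": float(np.exp(rng2.uniform(np.log(0.01), np.log(1)))),
                "gamma": float(np.exp(rng2.uniform(np.log(0.01), np.log(10)))),
            }
            svr = SVR(kernel="rbf", **cand).fit(Z, y)
            assert best["objective_value"] <= np.mean((svr.predict(Z) - y) ** 2) + 1e-12


class TestValidate:
    def _model(self, X, y):
        std = standardize_fit(X)
        return train_svr(std.transform(X), y, features=list(X.columns),
                         standardizer=std)

    def test_perfect_predictions(self, rng):
        X = pd.DataFrame({"a": np.linspace(-1, 1, 10)})
        y = X["a"].to_numpy()
        model = self._model(X, y)
        labels = np.array(["train"] * 7 + ["test"] * 3)
        pred = predict(model, X)
        rep = validate(model, X, pred, labels)  # score against its own output
        assert rep.R_all == pytest.approx(1.0)
        assert rep.MSE_all == pytest.approx(0.0, abs=1e-12)

    def test_offset_predictions_keep_r(self):
        y = np.linspace(0, 1, 10)
        r = qspr_model._safe_pearson(y + 0.1, y)
        assert r == pytest.approx(1.0)

    def test_affine_invariance_of_r(self):
        y = np.linspace(0, 1, 10)
        assert qspr_model._safe_pearson(3.2 * y + 0.7, y) == pytest.approx(1.0)

    def test_constant_predictions_leave_r_undefined(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(8)})
        model = train_svr(X, np.full(8, 1.0), features=["a"],
                          standardizer=None)
        labels = np.array(["train"] * 6 + ["test"] * 2)
        rep = validate(model, X, rng.standard_normal(8), labels)
        assert rep.R_train is None and rep.R_test is None
        assert np.isfinite(rep.MSE_train)


class TestFullPipeline:
    def test_end_to_end_determinism(self):
        desc, th, _ = synthetic_data.gen_qspr(seed=11)
        cfg = ModelConfig(split_seed=11)
        _, rep1, _ = fit_qspr(desc, th, cfg)
        _, rep2, _ = fit_qspr(desc, th, cfg)
        assert rep1 == rep2

    def test_constant_columns_never_selected(self):
        desc, th, meta = synthetic_data.gen_qspr(seed=4)
        model, _, _ = fit_qspr(desc, th, ModelConfig(split_seed=4))
        assert not set(model.features) & set(meta["constant"])

    def test_noiseless_benchmark_is_learnable(self):
        cfg_gen = synthetic_data.QsprConfig(sigma=0.0)
        r = []
        for s in range(1, 6):
            desc, th, _ = synthetic_data.gen_qspr(cfg_gen, seed=s)
            _, rep, _ = fit_qspr(desc, th, ModelConfig(split_seed=s))
            r.append(rep.R_test)
        assert np.median(r) >= 0.99

    def test_mlr_baseline_trails_svr_on_nonlinear_response(self):
        # ordinary least squares on the same selected, standardized
        # features: the bump-shaped response defeats a linear model
        from sklearn.linear_model import LinearRegression
        from scipy import stats as sps

        wins = 0
        for s in range(1, 6):
            desc, th, _ = synthetic_data.gen_qspr(seed=s)
            model, rep, pred = fit_qspr(desc, th, ModelConfig(split_seed=s))
            y = np.log10(th.to_numpy())
            Z = model.standardizer.transform(desc[model.features])
            tr = (pred["split"] == "train").to_numpy()
            lr = LinearRegression().fit(Z[tr], y[tr])
            r_mlr = sps.pearsonr(lr.predict(Z), y).statistic
            wins += rep.R_all > r_mlr
        assert wins >= 4
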