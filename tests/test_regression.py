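"""The four regressors and significance pruning, each checked against an
independent oracle (normal equations, pseudoinverse, exhaustive CART,
permutation test) rather than against itself."""

import numpy as np
import pandas as pd
import pytest

from enose.errors import CollinearityError, ConfigError, DomainError, SchemaError
from enose.regression import (
    ModelConfig,
    SignificanceReport,
    fit_elm,
    fit_mlr,
    fit_mnlr,
    fit_rf,
    model_from_dict,
    model_to_dict,
    predict,
    sensor_significance,
)
from enose.sensor_model import load_reference_pvalues


def _gaussian_design(n, p, seed, names=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)), columns=names or [f"s{j}" for j in range(p)]
    )


class TestSensorSignificance:
    def test_reference_pvalues_prune_to_eleven_sensors(self):
        """Thresholding the instrument's published per-sensor p-values at
        alpha=0.05 removes exactly MQ-135 and TGS822."""
        p = load_reference_pvalues()
        report = SignificanceReport.from_pvalues(p.to_dict(), alpha=0.05)
        assert set(report.removed) == {"MQ-135", "TGS822"}
        assert len(report.retained) == 11
        assert set(report.retained) | set(report.removed) == set(p.index)
        assert not set(report.retained) & set(report.removed)

    def test_perfect_predictor_has_vanishing_pvalue(self):
        X = _gaussian_design(200, 5, seed=0)
        y = X["s2"].to_numpy()
        report = sensor_significance(X, y)
        assert report.p_values["s2"] < 1e-10
        assert "s2" in report.retained

    def test_pvalues_match_permutation_oracle(self):
        """Coefficient t-test p-values agree with a 10,000-draw permutation
        distribution of the t statistic on a small Gaussian design."""
        n, p = 30, 4
        rng = np.random.default_rng(11)
        X = _gaussian_design(n, p, seed=12)
        y = 0.5 * X["s0"].to_numpy() + rng.normal(size=n)
        report = sensor_significance(X, y)

        A = np.column_stack([np.ones(n), X.to_numpy()])

        def t_stats(yv):
            beta, res_ss, *_ = np.linalg.lstsq(A, yv, rcond=None)
            resid = yv - A @ beta
            sigma2 = resid @ resid / (n - A.shape[1])
            cov = sigma2 * np.linalg.inv(A.T @ A)
            return beta[1:] / np.sqrt(np.diag(cov)[1:])

        observed = np.abs(t_stats(y))
        draws = np.empty((10_000, p))
        for i in range(10_000):
            draws[i] = np.abs(t_stats(rng.permutation(y)))
        perm_p = (draws >= observed).mean(axis=0)
        for j, name in enumerate(X.columns):
            assert report.p_values[name] == pytest.approx(perm_p[j], abs=0.03)

    def test_rank_deficient_design_raises_naming_columns(self):
        X = _gaussian_design(50, 3, seed=1)
        X["dup"] = X["s0"]
        with pytest.raises(CollinearityError, match="dup|s0"):
            sensor_significance(X, np.arange(50.0))

    def test_requires_more_rows_than_predictors(self):
        X = _gaussian_design(5, 4, seed=2)
        with pytest.raises(ConfigError):
            sensor_significance(X, np.arange(5.0))


class TestMLR:
    def test_noiseless_affine_recovery(self):
        X = _gaussian_design(100, 3, seed=3)
        y = 1.5 + X @ np.array([2.0, -1.0, 0.5])
        model = fit_mlr(X, y)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)
        resid = predict(model, X) - y
        assert np.abs(resid).max() < 1e-9
        assert model.params["intercept"] == pytest.approx(1.5, abs=1e-9)

    def test_coefficients_equal_normal_equations_solution(self):
        X = _gaussian_design(80, 4, seed=4)
        rng = np.random.default_rng(5)
        y = X @ np.array([1.0, 0.5, -2.0, 0.0]) + rng.normal(size=80)
        model = fit_mlr(X, y)
        A = np.column_stack([np.ones(80), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)  # independent solver
        got = [model.params["intercept"]] + [
            model.params["coef"][c] for c in X.columns
        ]
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_single_predictor_reduces_to_cov_over_var(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        y = 2.0 * x + rng.normal(size=60)
        X = pd.DataFrame({"x": x})
        model = fit_mlr(X, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.params["coef"]["x"] == pytest.approx(slope, rel=1e-10)

    def test_adjusted_r2_definition(self):
        X = _gaussian_design(50, 3, seed=7)
        rng = np.random.default_rng(8)
        y = X["s0"].to_numpy() + rng.normal(size=50)
        model = fit_mlr(X, y)
        n, p = 50, 3
        expected = 1 - (1 - model.r2) * (n - 1) / (n - p - 1)
        assert model.r2_adj == pytest.approx(expected, rel=1e-12)

    def test_duplicate_column_raises_unless_unchecked(self):
        X = _gaussian_design(50, 2, seed=9)
        X["dup"] = X["s1"]
        y = X["s0"].to_numpy()
        with pytest.raises(CollinearityError):
            fit_mlr(X, y)
        model = fit_mlr(X, y, rank_check=False)  # minimum-norm fallback
        assert np.abs(predict(model, X) - y).max() < 1e-8


class TestMNLR:
    def test_model_true_log_data_fits_exactly(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"x": rng.uniform(0.1, 5.0, size=80)})
        cfg = ModelConfig(log_offset=0.01)
        y = 3.0 + 2.0 * np.log(X["x"].to_numpy() + 0.01)
        model = fit_mnlr(X, y, cfg)
        assert model.r2 == pytest.approx(1.0, abs=1e-12)

    def test_equals_mlr_on_pretransformed_matrix(self):
        X = _gaussian_design(60, 3, seed=11).abs() + 0.5
        rng = np.random.default_rng(12)
        y = rng.normal(size=60)
        cfg = ModelConfig(log_offset=0.1)
        mnlr = fit_mnlr(X, y, cfg)
        mlr = fit_mlr(np.log(X + 0.1), y)
        assert mnlr.params["intercept"] == pytest.approx(mlr.params["intercept"])
        for c in X.columns:
            assert mnlr.params["coef"][c] == pytest.approx(mlr.params["coef"][c])

    def test_log_transform_wins_on_saturating_response(self):
        # saturating sensor-style response: y linear in log(x), so the log
        # transform must fit at least as well as the raw linear model
        rng = np.random.default_rng(13)
        x = rng.uniform(0.05, 1.0, size=400)
        y = 5.0 * np.log(x + 0.01) + rng.normal(scale=0.1, size=400)
        X = pd.DataFrame({"x": x})
        cfg = ModelConfig(log_offset=0.01)
        rmse_mnlr = np.sqrt(np.mean((predict(fit_mnlr(X, y, cfg), X) - y) ** 2))
        rmse_mlr = np.sqrt(np.mean((predict(fit_mlr(X, y), X) - y) ** 2))
        assert rmse_mnlr <= rmse_mlr

    def test_domain_error_below_log_offset(self):
        X = pd.DataFrame({"x": [-0.5, 1.0, 2.0]})
        with pytest.raises(DomainError):
            fit_mnlr(X, np.zeros(3), ModelConfig(log_offset=0.1))

    def test_response_transform_switch(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"x": rng.uniform(0.0, 1.0, size=100)})
        y = np.exp(1.0 + 2.0 * X["x"].to_numpy()) - 0.1
        cfg = ModelConfig(log_offset=0.1, mnlr_transform="response")
        model = fit_mnlr(X, y, cfg)
        np.testing.assert_allclose(predict(model, X), y, rtol=1e-8)


class TestELM:
    def test_affine_data_interpolated_with_identity_activation(self):
        X = _gaussian_design(100, 3, seed=15)
        y = 1.0 + X @ np.array([2.0, -1.0, 0.5])
        model = fit_elm(X, y, ModelConfig(nhid=15, seed=0))
        rmse = np.sqrt(np.mean((predict(model, X) - y) ** 2))
        assert rmse < 1e-8

    def test_output_weights_equal_minimum_norm_solve(self):
        X = _gaussian_design(20, 3, seed=16)
        rng = np.random.default_rng(17)
        y = rng.normal(size=20)
        cfg = ModelConfig(nhid=7, seed=3)
        model = fit_elm(X, y, cfg)
        W = np.asarray(model.params["weights"])
        b = np.asarray(model.params["biases"])
        H = X.to_numpy() @ W + b
        beta, *_ = np.linalg.lstsq(H, y, rcond=None)  # independent min-norm solve
        np.testing.assert_allclose(model.params["output_weights"], beta, atol=1e-8)

    def test_same_seed_reproduces_predictions(self):
        X = _gaussian_design(50, 4, seed=18)
        y = np.arange(50.0)
        p1 = predict(fit_elm(X, y, ModelConfig(seed=42)), X)
        p2 = predict(fit_elm(X, y, ModelConfig(seed=42)), X)
        np.testing.assert_array_equal(p1, p2)

    def test_identity_activation_predictions_independent_of_seed(self):
        # with g = identity and full-rank H, predictions live in the column
        # space of [X, 1] regardless of the random projection
        X = _gaussian_design(50, 4, seed=19)
        rng = np.random.default_rng(20)
        y = X @ np.array([1.0, 2.0, 0.0, -1.0]) + rng.normal(size=50)
        Xnew = _gaussian_design(10, 4, seed=21)
        p1 = predict(fit_elm(X, y, ModelConfig(seed=1)), Xnew)
        p2 = predict(fit_elm(X, y, ModelConfig(seed=2)), Xnew)
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_invalid_hidden_layer_size_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(nhid=0)


def exhaustive_cart(X: np.ndarray, y: np.ndarray, min_leaf: int) -> dict:
    """Brute-force CART regression tree: at every node enumerate all split
    points on all features and take the split minimizing the summed child
    variance (times child size).  Mirrors an unpruned variance-reducing tree."""
    node = {"value": float(y.mean())}
    n = len(y)
    if n < 2 * min_leaf or np.all(y == y[0]):
        return node
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        xs, ys = X[order, j], y[order]
        for i in range(min_leaf, n - min_leaf + 1):
            if xs[i - 1] == xs[i]:  # no threshold separates equal values
                continue
            left, right = ys[:i], ys[i:]
            cost = len(left) * left.var() + len(right) * right.var()
            if best is None or cost < best[0] - 1e-12:
                thr = (xs[i - 1] + xs[i]) / 2.0
                best = (cost, j, thr)
    if best is None:
        return node
    _, j, thr = best
    mask = X[:, j] <= thr
    if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
        return node
    node.update(
        feature=j,
        threshold=thr,
        left=exhaustive_cart(X[mask], y[mask], min_leaf),
        right=exhaustive_cart(X[~mask], y[~mask], min_leaf),
    )
    return node


def cart_predict(node: dict, x: np.ndarray) -> float:
    while "feature" in node:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return node["value"]


class TestRandomForest:
    def test_constant_target_predicts_constant(self):
        X = _gaussian_design(30, 3, seed=22)
        y = np.full(30, 4.2)
        model = fit_rf(X, y, ModelConfig(ntree=10, mtry=3, seed=0))
        np.testing.assert_allclose(predict(model, X), 4.2)

    def test_predictions_bounded_by_training_labels(self):
        X = _gaussian_design(100, 4, seed=23)
        rng = np.random.default_rng(24)
        y = rng.uniform(1.0, 8.0, size=100)
        model = fit_rf(X, y, ModelConfig(ntree=25, mtry=4, seed=0))
        p = predict(model, _gaussian_design(50, 4, seed=25))
        assert p.min() >= y.min() - 1e-9 and p.max() <= y.max() + 1e-9

    def test_single_tree_matches_exhaustive_split_oracle(self):
        # 12-row table, all predictors at every split, no bootstrap: the tree
        # must equal brute-force exhaustive CART
        rng = np.random.default_rng(26)
        X = pd.DataFrame(rng.uniform(size=(12, 2)), columns=["a", "b"])
        y = rng.uniform(1, 8, size=12)
        cfg = ModelConfig(ntree=1, mtry=2, bootstrap=False, seed=0, min_leaf=2)
        model = fit_rf(X, y, cfg)
        oracle = exhaustive_cart(X.to_numpy(), y, min_leaf=2)
        grid = pd.DataFrame(rng.uniform(size=(200, 2)), columns=["a", "b"])
        got = predict(model, grid)
        want = np.array([cart_predict(oracle, row) for row in grid.to_numpy()])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_invariant_to_monotone_feature_transforms(self):
        # split ranks are unchanged by strictly monotone transforms, so a
        # deterministic single tree gives identical predictions
        rng = np.random.default_rng(27)
        X = pd.DataFrame(rng.uniform(0.1, 2.0, size=(40, 2)), columns=["a", "b"])
        y = rng.uniform(1, 8, size=40)
        cfg = ModelConfig(ntree=1, mtry=2, bootstrap=False, seed=0, min_leaf=2)
        m_raw = fit_rf(X, y, cfg)
        Xm = pd.DataFrame({"a": np.log(X["a"]), "b": X["b"] ** 3})
        m_mono = fit_rf(Xm, y, cfg)
        # split ranks are unchanged, so every training point lands in the
        # same leaf (interior grid points may flip across transformed split
        # midpoints, so exact invariance is a training-sample property)
        np.testing.assert_allclose(
            predict(m_raw, X), predict(m_mono, Xm), atol=1e-10
        )
        oracle = exhaustive_cart(Xm.to_numpy(), y, min_leaf=2)
        want = np.array([cart_predict(oracle, row) for row in Xm.to_numpy()])
        np.testing.assert_allclose(predict(m_mono, Xm), want, atol=1e-10)

    def test_mtry_exceeding_predictors_rejected(self):
        X = _gaussian_design(20, 2, seed=28)
        with pytest.raises(ConfigError):
            fit_rf(X, np.arange(20.0), ModelConfig(ntree=5, mtry=4))


class TestPredictContract:
    def test_training_fit_reproduced(self):
        X = _gaussian_design(40, 3, seed=29)
        y = X @ np.array([1.0, 1.0, 1.0])
        model = fit_mlr(X, y)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-9)

    @pytest.mark.parametrize("kind", ["MLR", "MNLR", "ELM", "RF"])
    def test_column_order_permutation_is_irrelevant(self, kind):
        X = _gaussian_design(60, 3, seed=30).abs() + 0.5
        rng = np.random.default_rng(31)
        y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=60)
        cfg = ModelConfig(ntree=10, mtry=3, seed=0)
        model = {
            "MLR": lambda: fit_mlr(X, y),
            "MNLR": lambda: fit_mnlr(X, y, cfg),
            "ELM": lambda: fit_elm(X, y, cfg),
            "RF": lambda: fit_rf(X, y, cfg),
        }[kind]()
        shuffled = X[list(reversed(X.columns))]
        np.testing.assert_allclose(
            predict(model, shuffled), predict(model, X), atol=1e-12
        )

    def test_missing_feature_is_schema_error(self):
        X = _gaussian_design(30, 3, seed=32)
        model = fit_mlr(X, X @ np.ones(3))
        with pytest.raises(SchemaError):
            predict(model, X[["s0", "s1"]])

    @pytest.mark.parametrize("kind", ["MLR", "MNLR", "ELM", "RF"])
    def test_serialization_round_trip_preserves_predictions(self, kind):
        X = _gaussian_design(50, 3, seed=33).abs() + 0.5
        rng = np.random.default_rng(34)
        y = X @ np.array([2.0, 1.0, -0.5]) + rng.normal(size=50)
        cfg = ModelConfig(ntree=10, mtry=3, seed=0)
        model = {
            "MLR": lambda: fit_mlr(X, y),
            "MNLR": lambda: fit_mnlr(X, y, cfg),
            "ELM": lambda: fit_elm(X, y, cfg),
            "RF": lambda: fit_rf(X, y, cfg),
        }[kind]()
        restored = model_from_dict(model_to_dict(model))
        np.testing.assert_allclose(
            predict(restored, X), predict(model, X), atol=1e-10
        )


class TestCrossModelEquivalence:
    def test_identity_elm_equals_mlr_on_simulated_features(
        self, features_full_default
    ):
        """With identity activation and a full-rank hidden matrix the ELM is
        the same least-squares predictor as MLR."""
        X, meta, _ = features_full_default
        y = meta["label_abv"].to_numpy(dtype=float)
        mlr = fit_mlr(X, y)
        elm = fit_elm(X, y, ModelConfig(nhid=15, seed=5))
        np.testing.assert_allclose(predict(elm, X), predict(mlr, X), atol=1e-6)

    def test_mlr_coefficients_converge_to_truth(self):
        """Parameter recovery: coefficient error shrinks with noise and n."""
        truth = np.array([2.0, -1.0, 0.5])
        errs = {}
        for n in (100, 10_000):
            for noise in (0.5, 0.005):
                rng = np.random.default_rng(int(n + noise * 1000))
                X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
                y = X @ truth + rng.normal(scale=noise, size=n)
                model = fit_mlr(X, y)
                coef = np.array([model.params["coef"][c] for c in "abc"])
                errs[(n, noise)] = np.abs(coef - truth).max()
        assert errs[(100, 0.005)] < errs[(100, 0.5)]
        assert errs[(10_000, 0.5)] < errs[(100, 0.5)]
        assert errs[(10_000, 0.005)] < 1e-3
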