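import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from zoomfit.batch import SimulationBatch
from zoomfit.metamodel import (
    ModelError,
    Scaler,
    expand_polynomial,
    pca_fit,
    pca_project,
    pearson_matrix,
    plsr_fit,
    sensitivity_coefficients,
)


class TestScaler:
    def test_columns_standardized_with_sample_sd(self):
        s = Scaler.fit(np.array([[1.0], [2.0], [3.0]]))
        z = s.transform(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(z.ravel(), [-1, 0, 1])  # SD = 1 with n-1 convention

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4)) * [1, 10, 0.1, 100] + [0, -5, 3, 1e4]
        s = Scaler.fit(X)
        assert np.allclose(s.inverse_transform(s.transform(X)), X)

    def test_constant_column_dropped_with_warning_and_restored(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            s = Scaler.fit(X)
        z = s.transform(X)
        assert z.shape[1] == 1
        assert np.allclose(s.inverse_transform(z), X)


class TestPolynomialExpansion:
    def test_two_variable_layout(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        Xe, names, base = expand_polynomial(X, ["x1", "x2"])
        assert names == ["x1", "x2", "x1^2", "x2^2", "x1*x2"]
        assert np.allclose(Xe[0], [1, 2, 1, 4, 2])
        assert base["x1*x2"] == ("x1", "x2")

    @pytest.mark.parametrize("p,expected", [(1, 2), (2, 5), (13, 104)])
    def test_expanded_dimension(self, p, expected):
        Xe, names, _ = expand_polynomial(np.ones((3, p)))
        assert Xe.shape[1] == len(names) == expected


class TestPLSR:
    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            X = rng.normal(size=(20, 5))
            B = rng.normal(size=(5, 2))
            Y = X @ B + rng.normal(size=(20, 1)) * 0  # exactly linear
            m = plsr_fit(X, Y, ncomp=5)
            assert np.allclose(m.predict(X), Y, atol=1e-8)
            # standardized coefficients match the OLS solution on the same scaling
            Xs = m.scaler_x.transform(X)
            Ys = m.scaler_y.transform(Y)
            B_ols = np.linalg.lstsq(
                np.column_stack([np.ones(len(Xs)), Xs]), Ys, rcond=None
            )[0][1:]
            assert np.max(np.abs(m.coefficients - B_ols)) < 1e-6

    def test_single_predictor_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 3.0 * x + rng.normal(size=40)
        m = plsr_fit(x[:, None], y, ncomp=1)
        _, B = m.raw_coefficients()
        expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert B[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_constant_response_gives_zero_coefficients(self):
        X = np.random.default_rng(2).normal(size=(15, 3))
        Y = np.full((15, 1), 4.2)
        with pytest.warns(UserWarning, match="zero-variance"):
            m = plsr_fit(X, Y, ncomp=2)
        _, B = m.raw_coefficients()
        assert np.allclose(B, 0.0)
        assert np.allclose(m.predict(X), 4.2)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 8))
        Y = np.sin(X[:, :2]).sum(axis=1)[:, None] + X[:, 2:3] ** 2
        m = plsr_fit(X, Y, ncomp=5)
        G = m.x_scores.T @ m.x_scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_excessive_ncomp_capped_with_warning(self):
        X = np.random.default_rng(4).normal(size=(10, 3))
        Y = X.sum(axis=1)
        with pytest.warns(UserWarning, match="capping"):
            m = plsr_fit(X, Y, ncomp=50)
        assert m.ncomp <= 3

    def test_nan_rows_rejected(self):
        X = np.ones((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ModelError):
            plsr_fit(X, np.ones(5), ncomp=1)

    def test_against_independent_pls_implementation(self):
        # cross-check predictions with scikit-learn's NIPALS PLSRegression
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        Y = np.column_stack([X[:, 0] + 2 * X[:, 1], X[:, 2] ** 2])
        Y += rng.normal(size=Y.shape) * 0.1
        for a in (1, 3, 6):
            mine = plsr_fit(X, Y, ncomp=a)
            ref = PLSRegression(n_components=a, scale=True).fit(X, Y)
            # sklearn standardizes with n-1 SD too; its inner power iteration
            # stops at tol 1e-6, hence the loose comparison
            assert np.allclose(mine.predict(X), ref.predict(X), atol=2e-3)
        # single response: the first weight vector is closed-form, so full
        # agreement is exact to numerical precision
        y1 = Y[:, :1]
        mine = plsr_fit(X, y1, ncomp=4)
        ref = PLSRegression(n_components=4, scale=True).fit(X, y1)
        assert np.allclose(mine.predict(X), ref.predict(X), atol=1e-8)


class TestSensitivity:
    def test_irrelevant_input_has_negligible_coefficients(self):
        rng = np.random.default_rng(11)
        params = pd.DataFrame(
            {"x1": rng.uniform(-1, 1, 300), "x2": rng.uniform(-1, 1, 300)}
        )
        metrics = pd.DataFrame({"y": np.tanh(params["x1"]) + 0.5 * params["x1"] ** 2})
        batch = SimulationBatch(params, metrics)
        res = sensitivity_coefficients(batch, ncomp=5)
        coef = res.coefficients["y"]
        x2_mag = max(abs(coef["x2"]), abs(coef["x2^2"]), abs(coef["x1*x2"]))
        assert x2_mag < 0.05 * abs(coef["x1"])

    def test_standardized_ratio_for_known_linear_map(self):
        rng = np.random.default_rng(12)
        params = pd.DataFrame(
            {"x1": rng.uniform(0, 1, 400), "x2": rng.uniform(0, 1, 400)}
        )
        metrics = pd.DataFrame({"y": params["x1"] + 10 * params["x2"]})
        res = sensitivity_coefficients(SimulationBatch(params, metrics), ncomp=5)
        coef = res.coefficients["y"]
        assert abs(coef["x2"]) / abs(coef["x1"]) == pytest.approx(10.0, rel=0.05)

    def test_invariant_under_affine_input_rescaling(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(-1, 1, 200)
        metrics = pd.DataFrame({"y": x + x**2})
        a = sensitivity_coefficients(
            SimulationBatch(pd.DataFrame({"x": x}), metrics), ncomp=2
        ).coefficients
        b = sensitivity_coefficients(
            SimulationBatch(pd.DataFrame({"x": 100 * x + 7}), metrics), ncomp=2
        ).coefficients
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_under_determined_batch_rejected(self):
        params = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        params.columns = ["a", "b", "c"]
        metrics = pd.DataFrame({"y": np.arange(4.0)})
        with pytest.raises(ModelError, match="under-determined"):
            sensitivity_coefficients(SimulationBatch(params, metrics))


class TestPearsonMatrix:
    def test_structure_and_exact_values(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=100)
        params = pd.DataFrame({"x": x})
        metrics = pd.DataFrame({"neg": -x, "noise": rng.normal(size=100)})
        R = pearson_matrix(SimulationBatch(params, metrics))
        assert R.loc["x", "x"] == pytest.approx(1.0)
        assert R.loc["x", "neg"] == pytest.approx(-1.0)
        assert np.allclose(R.to_numpy(), R.to_numpy().T, equal_nan=True)
        assert np.nanmax(np.abs(R.to_numpy())) <= 1.0 + 1e-12

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(22)
        params = pd.DataFrame({"a": rng.uniform(size=500)})
        metrics = pd.DataFrame({"b": rng.uniform(size=500)})
        R = pearson_matrix(SimulationBatch(params, metrics))
        assert abs(R.loc["a", "b"]) < 0.15

    def test_constant_column_reported_missing(self):
        params = pd.DataFrame({"a": np.arange(5.0), "c": np.ones(5)})
        metrics = pd.DataFrame({"y": np.arange(5.0) ** 2})
        R = pearson_matrix(SimulationBatch(params, metrics))
        assert np.isnan(R.loc["c", "a"]) and np.isnan(R.loc["y", "c"])


class TestPCA:
    def test_collinear_data_needs_one_component(self):
        x = np.linspace(0, 1, 30)
        m = pca_fit(np.column_stack([x, 3 * x]))
        assert m.k99 == 1
        assert m.explained_variance_fractions[0] == pytest.approx(1.0)

    def test_k99_from_cumulative_fractions(self):
        rng = np.random.default_rng(31)
        # variances engineered so PC fractions are ~[0.95, 0.04, 0.01]
        Z = rng.normal(size=(4000, 3)) * np.sqrt([0.95, 0.04, 0.01])
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m = pca_fit(Z @ Q.T * [1, 1, 1])
        # standardization rescales; check the definition on the model's own fractions
        cum = np.cumsum(m.explained_variance_fractions)
        assert m.k99 == int(np.searchsorted(cum, 0.99) + 1)

    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(25, 4))
        m = pca_fit(X)
        s = pca_project(m, X.mean(axis=0, keepdims=True))
        assert np.allclose(s, 0.0, atol=1e-10)

    def test_reconstruction_error_decreases(self):
        rng = np.random.default_rng(33)
        X = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        m = pca_fit(X)
        Z = m.scaler.transform(X)
        errs = []
        for k in range(1, m.loadings.shape[0] + 1):
            L = m.loadings[:k]
            errs.append(np.linalg.norm(Z - (Z @ L.T) @ L))
        assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(errs, errs[1:]))
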