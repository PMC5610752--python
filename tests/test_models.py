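import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from qsarforge import MLR, RBFSVR, SvrConfig
from qsarforge.exceptions import ConfigurationError, SingularFitError
from qsarforge.synth import SynthConfig, generate


class TestMLR:
    def test_matches_normal_equations_oracle(self):
        """6-point, 2-descriptor fit equals an explicit (X'X)^-1 X'y solve."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        res = MLR(y, X).fit()
        design = np.column_stack([np.ones(6), X])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-10)
        # standard errors from unbiased sigma^2 * diag((X'X)^-1)
        resid = y - design @ beta
        s2 = resid @ resid / (6 - 3)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(design.T @ design)))
        np.testing.assert_allclose(res.std_errors.to_numpy(), se, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, clean_dataset):
        table = clean_dataset.table
        subset = table.descriptor_names[:5]
        res = MLR.from_table(table, subset).fit()
        design = np.column_stack([np.ones(table.n_compounds),
                                  table.select_descriptors(subset).X])
        np.testing.assert_allclose(design.T @ res.resid, 0.0, atol=1e-8)

    def test_equation_layout(self, tiny_table):
        res = MLR.from_table(tiny_table, ["a", "b"]).fit()
        eq = res.equation()
        assert eq.startswith("pIC50 = ")
        assert eq.count("(±") == 3  # intercept + 2 descriptors
        assert "a" in eq and "b" in eq

    def test_rank_deficient_design_rejected(self):
        X = np.ones((8, 2))
        X[:, 1] = np.arange(8.0)
        X = np.column_stack([X[:, 1], 2 * X[:, 1]])  # perfectly collinear
        with pytest.raises(SingularFitError):
            MLR(np.arange(8.0), X).fit()

    def test_prediction_on_query_table(self, clean_dataset):
        ds = clean_dataset
        res = MLR.from_table(ds.table, ds.true_subset).fit()
        direct = (res.intercept
                  + ds.table.data[ds.true_subset].to_numpy()
                  @ res.coefficients.to_numpy())
        np.testing.assert_allclose(res.predict(ds.table), direct, atol=1e-10)


class TestSVR:
    def test_constant_targets_predicted_within_epsilon(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.full(10, 6.5)
        res = RBFSVR(y, X).fit(SvrConfig(C=10, epsilon=0.05, gamma=1.0))
        assert np.abs(res.predict(X) - 6.5).max() <= 0.05 + 1e-9

    def test_predictions_match_dual_qp_oracle(self):
        """sklearn path agrees with an independently solved dual QP <= 1e-4."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(5, 2))
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.2])
        cfg = SvrConfig(C=10.0, epsilon=0.1, gamma=0.5)
        res = RBFSVR(y, X).fit(cfg)

        Xs = (X - X.mean(0)) / X.std(0)
        ys = (y - y.mean()) / y.std()
        n = len(ys)
        K = np.exp(-cfg.gamma * cdist(Xs, Xs) ** 2)

        def neg_dual(th):
            d = th[:n] - th[n:]
            return 0.5 * d @ K @ d + cfg.epsilon * th.sum() - ys @ d

        best = None
        for trial in range(5):
            start = np.random.default_rng(trial).uniform(0, 1, 2 * n)
            sol = minimize(
                neg_dual, start, method="SLSQP",
                bounds=[(0, cfg.C)] * (2 * n),
                constraints=[{"type": "eq",
                              "fun": lambda th: np.sum(th[:n] - th[n:])}],
                options={"maxiter": 2000, "ftol": 1e-14})
            if best is None or sol.fun < best.fun:
                best = sol
        d = best.x[:n] - best.x[n:]
        f0 = K @ d
        b_candidates = []
        for i in range(n):
            if 1e-6 < best.x[i] < cfg.C - 1e-6:
                b_candidates.append(ys[i] - f0[i] - cfg.epsilon)
            if 1e-6 < best.x[n + i] < cfg.C - 1e-6:
                b_candidates.append(ys[i] - f0[i] + cfg.epsilon)
        oracle = (f0 + np.mean(b_candidates)) * y.std() + y.mean()
        np.testing.assert_allclose(res.predict(X), oracle, atol=1e-4)
        # points strictly inside the eps tube must carry zero dual weight
        inside = np.abs(ys - (f0 + np.mean(b_candidates))) < cfg.epsilon - 1e-6
        assert np.abs(d[inside]).max(initial=0.0) < 1e-6

    def test_single_point_grid_returned(self, clean_dataset):
        ds = clean_dataset
        res = RBFSVR.from_table(ds.table, ds.true_subset).tune_and_fit(
            {"C": [50.0], "epsilon": [0.01], "gamma": [5.0]})
        assert (res.config.C, res.config.epsilon, res.config.gamma) == (50.0, 0.01, 5.0)
        assert res.loo_rmse_ is not None

    def test_tie_break_prefers_smaller_c_gamma_epsilon(self):
        # constant targets: every triple gives identical LOO-RMSE
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        y = np.full(8, 5.0)
        res = RBFSVR(y, X).tune_and_fit(
            {"C": [10.0, 1.0], "epsilon": [0.1, 0.01], "gamma": [2.0, 1.0]})
        assert (res.config.C, res.config.gamma, res.config.epsilon) == (1.0, 1.0, 0.01)

    def test_empty_grid_rejected(self, clean_dataset):
        with pytest.raises(ConfigurationError):
            RBFSVR.from_table(clean_dataset.table,
                              clean_dataset.true_subset).tune_and_fit({"C": []})

    def test_svr_beats_mlr_on_nonlinear_data(self):
        ds = generate(SynthConfig(n_compounds=35, n_descriptors=20,
                                  k_informative=5, n_constant=0,
                                  n_near_constant=0, n_collinear_pairs=0,
                                  noise_sd=0.2, nonlinear=True, seed=23))
        mlr = MLR.from_table(ds.table, ds.true_subset).fit()
        svr = RBFSVR.from_table(ds.table, ds.true_subset).tune_and_fit()
        assert svr.rsquared >= mlr.rsquared
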