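import numpy as np
import pytest

from icnet.smap import (
    SmapConfig,
    build_interaction_tensor,
    fit_multivariate_smap,
)
from tests.conftest import make_ricker_truth


def var1(A, n, noise_sd, seed=0):
    rng = np.random.default_rng(seed)
    k = A.shape[0]
    X = np.zeros((n, k))
    X[0] = rng.normal(size=k)
    for t in range(n - 1):
        X[t + 1] = A @ X[t] + rng.normal(0, noise_sd, k)
    return X


def rotation(angle=0.7, scale=0.98):
    c, s = np.cos(angle), np.sin(angle)
    return scale * np.array([[c, -s], [s, c]])


A_VAR = np.array([[0.5, 0.2], [0.1, 0.4]])
NO_COV = dict(include_temperature_trend=False, include_intercept=False)


class TestGlobalLimits:
    def test_theta_zero_lambda_zero_equals_ols_everywhere(self):
        """theta=0 removes the local weighting, so every coefficient row
        equals the one global least-squares solution."""
        X = var1(A_VAR, 300, 0.1, seed=1)
        fit = fit_multivariate_smap(
            X[:, 0], X, config=SmapConfig(theta=0.0, ridge_lambda=0.0, **NO_COV)
        )
        beta = np.linalg.lstsq(X[:-1], X[1:, 0], rcond=None)[0]
        assert np.abs(fit.coefficients - beta).max() < 1e-8

    def test_theta_zero_matches_ridge_closed_form(self):
        lam = 0.37
        X = var1(A_VAR, 300, 0.1, seed=2)
        fit = fit_multivariate_smap(
            X[:, 0], X, config=SmapConfig(theta=0.0, ridge_lambda=lam, **NO_COV)
        )
        Z, y = X[:-1], X[1:, 0]
        beta = np.linalg.solve(Z.T @ Z + lam * np.eye(2), Z.T @ y)
        assert np.abs(fit.coefficients - beta).max() < 1e-8

    def test_noise_free_linear_system_recovers_A(self):
        """On x(t+1) = A x(t) with no noise the coefficients equal A to
        1e-4 elementwise at n = 500."""
        A = rotation()
        X = var1(A, 500, 0.0, seed=3)
        rows = [
            fit_multivariate_smap(
                X[:, i], X,
                config=SmapConfig(theta=0.0, ridge_lambda=0.0, **NO_COV),
            ).coefficients[0]
            for i in range(2)
        ]
        assert np.abs(np.vstack(rows) - A).max() < 1e-4


class TestRegularizationAndLocality:
    def test_shrinkage_is_monotone_in_lambda(self):
        """For fixed weights every |coefficient| is non-increasing as the
        ridge penalty grows."""
        X = var1(A_VAR, 200, 0.1, seed=4)
        lams = [0.0, 0.1, 1.0, 10.0, 100.0]
        norms = []
        for lam in lams:
            fit = fit_multivariate_smap(
                X[:, 0], X,
                config=SmapConfig(theta=1.3, ridge_lambda=lam, **NO_COV),
            )
            norms.append(np.abs(fit.coefficients).sum(axis=1))
        for a, b in zip(norms, norms[1:]):
            assert (b <= a + 1e-10).all()

    def test_state_dependence_helps_on_nonlinear_dynamics(self):
        """On the oscillatory Ricker pair the cross-validated theta is
        positive and the local fit beats the global linear one."""
        truth = make_ricker_truth(n_steps=200, seed=6)
        from icnet.prep import standardize

        x0 = standardize(truth.abundances.values[0, :, 0])
        x1 = standardize(truth.abundances.values[1, :, 0])
        X = np.column_stack([x0, x1])
        cfg = SmapConfig(include_temperature_trend=False)
        fit = fit_multivariate_smap(x0, X, config=cfg)
        global_fit = fit_multivariate_smap(
            x0, X,
            config=SmapConfig(
                theta=0.0, ridge_lambda=fit.ridge_lambda,
                include_temperature_trend=False,
            ),
        )
        assert fit.theta > 0
        assert fit.loo_rmse <= global_fit.loo_rmse

    def test_singular_design_with_zero_lambda_raises(self):
        X = np.column_stack([np.arange(50.0), 2 * np.arange(50.0)])
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_multivariate_smap(
                X[:, 0], X,
                config=SmapConfig(theta=0.0, ridge_lambda=0.0, **NO_COV),
            )

    def test_p_not_less_than_n_with_zero_lambda_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 8))
        with pytest.raises(ValueError, match="lambda"):
            fit_multivariate_smap(
                X[:, 0], X,
                config=SmapConfig(theta=0.0, ridge_lambda=0.0, **NO_COV),
            )

    def test_many_predictors_warns_on_reliability(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 7))
        with pytest.warns(UserWarning, match="unreliable"):
            fit_multivariate_smap(
                X[:, 0], X,
                config=SmapConfig(theta=0.0, ridge_lambda=0.1, **NO_COV),
            )


class TestJacobianRecovery:
    def test_tracks_analytic_ricker_jacobian(self, ricker_truth):
        """Median temporal correlation between interspecific S-map
        coefficients and the exact Jacobian entries exceeds 0.7."""
        cfg = SmapConfig(include_temperature_trend=False)
        tensor = build_interaction_tensor(
            [(0, 1), (1, 0)], ricker_truth.abundances, config=cfg
        )
        J = ricker_truth.jacobians[0]
        cors = []
        for i, j in [(0, 1), (1, 0)]:
            tt = np.where(tensor.valid[0, :, i, j])[0]
            tt = tt[tt < J.shape[0]]
            cors.append(
                np.corrcoef(tensor.coefficients[0, tt, i, j], J[tt, i, j])[0, 1]
            )
        assert np.median(cors) > 0.7


class TestInteractionTensor:
    def test_empty_link_set_gives_diagonal_only_tensor(self, ricker_truth):
        cfg = SmapConfig(theta=0.5, ridge_lambda=0.01,
                         include_temperature_trend=False)
        tensor = build_interaction_tensor([], ricker_truth.abundances,
                                          config=cfg)
        off = ~np.eye(2, dtype=bool)
        assert not tensor.valid[:, :, off].any()
        assert tensor.valid[:, :, np.eye(2, dtype=bool)].any()

    def test_support_restricted_to_detected_links(self, five_species_truth):
        links = [(0, 1), (4, 3)]
        cfg = SmapConfig(theta=0.5, ridge_lambda=0.01,
                         include_temperature_trend=False)
        tensor = build_interaction_tensor(
            links, five_species_truth.abundances, config=cfg
        )
        valid_off = tensor.valid[0].any(axis=0)
        np.fill_diagonal(valid_off, False)
        assert {(j, i) for i, j in zip(*np.where(valid_off))} == {
            (0, 1), (4, 3)
        }

    def test_fitted_sign_matches_jacobian_direction(self, ricker_truth):
        """A suppressive coupling (A_21 > 0) yields negative interspecific
        Jacobian entries; the fitted coefficients agree in sign on
        average."""
        cfg = SmapConfig(include_temperature_trend=False)
        tensor = build_interaction_tensor(
            [(0, 1), (1, 0)], ricker_truth.abundances, config=cfg
        )
        mean_is = np.nanmean(
            np.where(tensor.valid[0], tensor.coefficients[0], np.nan), axis=0
        )
        J_mean = ricker_truth.jacobians[0].mean(axis=0)
        assert np.sign(mean_is[1, 0]) == np.sign(J_mean[1, 0])
        assert np.sign(mean_is[0, 1]) == np.sign(J_mean[0, 1])

    def test_long_frame_and_edge_list_round_trip(self, ricker_truth):
        cfg = SmapConfig(theta=0.5, ridge_lambda=0.01,
                         include_temperature_trend=False)
        tensor = build_interaction_tensor(
            [(0, 1)], ricker_truth.abundances, config=cfg
        )
        df = tensor.to_long_frame()
        assert set(df.columns) == {"plot", "date", "cause", "effect", "IS"}
        edges = tensor.static_edge_list()
        assert (edges["abs_IS"] >= 0).all()
        assert (edges["cause"] != edges["effect"]).all()


class TestSmapConfig:
    def test_cv_with_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            SmapConfig(theta="cv", theta_grid=())

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            SmapConfig(theta=-1.0)
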