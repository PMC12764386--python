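"""GP engine: kernel algebra, marginal likelihood, MLE, BLUP prediction."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gpsc import (
    GPModel,
    KernelParams,
    ParamBounds,
    blup_predict,
    fit_gp_mle,
    log_marginal_likelihood,
    rbf_kernel,
)
from gpsc.gp import JITTER


def _dense_gram(X, params):
    """Independent Gram construction: explicit loops, explicit nugget."""
    n = X.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for k in range(n):
            d2 = np.sum((X[i] - X[k]) ** 2)
            K[i, k] = params.sigma2 * math.exp(-d2 / (2 * params.b))
    return K + (params.tau2 + JITTER * params.sigma2) * np.eye(n)


class TestRbfKernel:
    def test_zero_distance_gives_sigma2(self, toy_params):
        A = np.array([[0.3, 0.4]])
        assert rbf_kernel(A, A, toy_params)[0, 0] == pytest.approx(toy_params.sigma2)

    def test_printed_formula_value(self):
        # sigma2=1, b=1, squared distance 2 -> exp(-1)
        params = KernelParams(sigma2=1.0, b=1.0)
        A = np.array([[0.0]])
        B = np.array([[math.sqrt(2.0)]])
        assert rbf_kernel(A, B, params)[0, 0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_monotone_decay_with_distance(self, toy_params):
        A = np.zeros((1, 2))
        dists = np.linspace(0, 10, 50)
        B = np.column_stack([dists, np.zeros(50)])
        vals = rbf_kernel(A, B, toy_params)[0]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 1e-6 * toy_params.sigma2

    def test_symmetry_and_psd_random_designs(self, rng, toy_params):
        for _ in range(5):
            X = rng.normal(size=(rng.integers(2, 50), 3))
            K = rbf_kernel(X, X, toy_params)
            assert np.array_equal(K, K.T)
            eigmin = np.linalg.eigvalsh(K).min()
            assert eigmin >= -1e-8 * toy_params.sigma2

    def test_entries_bounded_by_sigma2(self, rng, toy_params):
        A = rng.normal(size=(10, 2))
        B = rng.normal(size=(7, 2))
        K = rbf_kernel(A, B, toy_params)
        assert np.all(K > 0) and np.all(K <= toy_params.sigma2)

    def test_dimension_mismatch_rejected(self, toy_params):
        with pytest.raises(ValueError, match="column"):
            rbf_kernel(np.zeros((2, 2)), np.zeros((2, 3)), toy_params)

    @pytest.mark.parametrize("bad", [dict(sigma2=-1.0, b=1.0), dict(sigma2=1.0, b=0.0)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            KernelParams(**bad)


class TestLogMarginalLikelihood:
    def test_single_standard_normal_point(self):
        # n=1, K = 1 (+jitter), Y=0: log N(0|0,1) = -0.5 log(2 pi)
        val = log_marginal_likelihood(
            np.array([[0.0]]), np.array([0.0]), KernelParams(sigma2=1.0, b=1.0)
        )
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-7)

    def test_matches_dense_two_point_oracle(self, toy_params):
        X = np.array([[0.0, 0.0], [1.0, 0.5]])
        Y = np.array([0.7, -0.4])
        K = _dense_gram(X, toy_params)
        expected = -0.5 * Y @ np.linalg.inv(K) @ Y - 0.5 * math.log(
            np.linalg.det(K)
        ) - math.log(2 * math.pi)
        assert log_marginal_likelihood(X, Y, toy_params) == pytest.approx(expected, abs=1e-10)

    def test_response_scaling_follows_closed_form(self, toy_params, five_point_data):
        # log p(cY) = log p(Y) - 0.5 (c^2 - 1) Y' K^{-1} Y
        X, Y = five_point_data
        c = 2.5
        K = _dense_gram(X, toy_params)
        quad = Y @ np.linalg.inv(K) @ Y
        base = log_marginal_likelihood(X, Y, toy_params)
        scaled = log_marginal_likelihood(X, c * Y, toy_params)
        assert scaled - base == pytest.approx(-0.5 * (c**2 - 1) * quad, rel=1e-9)


class TestFitGpMle:
    def test_constant_zero_response_drives_sigma2_to_floor(self):
        X = np.linspace(0, 1, 12)[:, None]
        model = fit_gp_mle(X, np.zeros(12), seed=0)
        # zero variance falls back to unit-variance default bounds; sigma2
        # must sit at/near the bottom of the box actually used
        floor = ParamBounds.default(1.0).sigma2[0]
        assert model.params.sigma2 <= floor * 10

    def test_same_seed_gives_identical_params(self, rng):
        X = rng.uniform(size=(30, 2))
        Y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.1, 30)
        m1 = fit_gp_mle(X, Y, seed=42)
        m2 = fit_gp_mle(X, Y, seed=42)
        assert m1.params == m2.params

    def test_fitted_params_lie_within_bounds(self, rng):
        X = rng.uniform(size=(40, 2))
        Y = np.cos(4 * X[:, 1]) + rng.normal(0, 0.2, 40)
        bounds = ParamBounds(sigma2=(0.01, 50.0), b=(0.05, 20.0), tau2=(1e-6, 5.0))
        model = fit_gp_mle(X, Y, bounds=bounds, seed=1)
        assert bounds.contains(model.params)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_gp_mle(np.empty((0, 2)), np.empty(0))

    def test_mle_not_worse_than_alternative_params(self, rng):
        X = rng.uniform(size=(25, 2))
        Y = np.sin(5 * X[:, 0]) * X[:, 1] + rng.normal(0, 0.1, 25)
        Yc = Y - Y.mean()
        model = fit_gp_mle(X, Y, seed=3)
        fitted = log_marginal_likelihood(X, Yc, model.params)
        bounds = ParamBounds.default(Yc.var())
        lo, hi = bounds.as_arrays()
        for _ in range(10):
            trial = KernelParams(*np.exp(rng.uniform(np.log(lo), np.log(hi))))
            assert fitted >= log_marginal_likelihood(X, Yc, trial) - 1e-6

    def test_recovers_generating_hyperparameters(self):
        """Data simulated from a known GP: fitted (sigma2, b, tau2) within a
        factor of 2 of truth in the median over 10 seeds."""
        true = KernelParams(sigma2=2.0, b=0.3, tau2=0.05)
        n = 200
        ratios = []
        for seed in range(10):
            g = np.random.default_rng(seed)
            X = g.uniform(0, 1, size=(n, 2))
            K = rbf_kernel(X, X, true) + true.tau2 * np.eye(n)
            Y = np.linalg.cholesky(K + 1e-10 * np.eye(n)) @ g.standard_normal(n)
            m = fit_gp_mle(X, Y, seed=seed, restarts=2)
            ratios.append(
                [m.params.sigma2 / true.sigma2, m.params.b / true.b, m.params.tau2 / true.tau2]
            )
        med = np.median(ratios, axis=0)
        assert np.all(med >= 0.5) and np.all(med <= 2.0)


class TestBlupPredict:
    def test_matches_explicit_inverse_oracle(self, toy_params, five_point_data):
        X, Y = five_point_data
        Yc = Y - Y.mean()
        model = GPModel(params=toy_params, train_inputs=X, train_targets=Yc, y_offset=Y.mean())
        Xstar = np.array([[0.5, 0.5], [0.0, 1.0], [0.25, 0.75]])
        K = _dense_gram(X, toy_params)
        Ks = toy_params.sigma2 * np.exp(
            -cdist(Xstar, X, "sqeuclidean") / (2 * toy_params.b)
        )
        expected = Ks @ np.linalg.inv(K) @ Yc + Y.mean()
        assert np.allclose(blup_predict(model, Xstar), expected, atol=1e-10)

    def test_noise_free_interpolation_at_training_points(self, five_point_data):
        X, Y = five_point_data
        params = KernelParams(sigma2=1.5, b=0.5, tau2=0.0)
        model = GPModel(params=params, train_inputs=X, train_targets=Y)
        assert np.allclose(blup_predict(model, X), Y, atol=1e-6)

    def test_far_field_returns_prior_mean(self, five_point_data):
        X, Y = five_point_data
        params = KernelParams(sigma2=1.0, b=0.2, tau2=0.01)
        offset = 3.7
        model = GPModel(params=params, train_inputs=X, train_targets=Y - offset, y_offset=offset)
        far = np.array([[100.0, 100.0]])
        assert blup_predict(model, far)[0] == pytest.approx(offset, abs=1e-8)

    def test_linear_in_response(self, toy_params, five_point_data, rng):
        X, _ = five_point_data
        Y1 = rng.normal(size=5)
        Y2 = rng.normal(size=5)
        Xstar = rng.uniform(size=(4, 2))

        def pred(Y):
            m = GPModel(params=toy_params, train_inputs=X, train_targets=Y)
            return blup_predict(m, Xstar)

        assert np.allclose(pred(Y1 + Y2), pred(Y1) + pred(Y2), atol=1e-10)

    def test_dimension_mismatch_rejected(self, toy_params, five_point_data):
        X, Y = five_point_data
        model = GPModel(params=toy_params, train_inputs=X, train_targets=Y)
        with pytest.raises(ValueError, match="columns"):
            blup_predict(model, np.zeros((2, 3)))


class TestSklearnCrossCheck:
    """Agreement with an independently implemented GP (scikit-learn), using
    the length-scale mapping l = sqrt(b)."""

    def test_predictions_match_fixed_kernel_gpr(self, five_point_data):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        X, Y = five_point_data
        params = KernelParams(sigma2=1.8, b=0.6, tau2=0.09)
        skl = GaussianProcessRegressor(
            kernel=ConstantKernel(params.sigma2, "fixed")
            * RBF(math.sqrt(params.b), "fixed"),
            alpha=params.tau2 + JITTER * params.sigma2,
            optimizer=None,
            normalize_y=False,
        ).fit(X, Y)
        model = GPModel(params=params, train_inputs=X, train_targets=Y)
        Xstar = np.array([[0.3, 0.3], [0.8, 0.1]])
        assert np.allclose(blup_predict(model, Xstar), skl.predict(Xstar), atol=1e-8)

    def test_log_marginal_likelihood_matches(self, five_point_data):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        X, Y = five_point_data
        params = KernelParams(sigma2=1.8, b=0.6, tau2=0.09)
        kern = ConstantKernel(params.sigma2, "fixed") * RBF(
            math.sqrt(params.b), "fixed"
        ) + WhiteKernel(params.tau2 + JITTER * params.sigma2, "fixed")
        skl = GaussianProcessRegressor(kernel=kern, alpha=0.0, optimizer=None).fit(X, Y)
        ours = log_marginal_likelihood(X, Y, params)
        assert ours == pytest.approx(skl.log_marginal_likelihood(), abs=1e-8)
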