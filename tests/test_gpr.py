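"""Gaussian-process regression: kernels, interpolation, tuning, metrics."""

import numpy as np
import pytest

from ppgbp import gpr
from ppgbp.errors import IllConditionedError, InvalidArgumentError, SchemaError


@pytest.mark.parametrize("family", ["exponential", "matern52", "rbf"])
def test_kernel_matrices_are_positive_semidefinite(family):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 5))
    K = gpr.kernel_matrix(family, 0.3, X)
    assert np.allclose(K, K.T)
    assert np.linalg.eigvalsh(K).min() >= -1e-8


def test_kernel_config_validation():
    with pytest.raises(InvalidArgumentError):
        gpr.KernelConfig(family="cubic")
    with pytest.raises(InvalidArgumentError):
        gpr.KernelConfig(sigma=0.0)
    with pytest.raises(InvalidArgumentError):
        gpr.KernelConfig(noise_level=-1.0)


class TestFitPredict:
    def test_single_point_is_interpolated_exactly(self):
        m = gpr.GaussianProcessBP("matern52", 0.2, noise_level=0.0,
                                  standardize=False).fit([[0.0]], [87.0])
        assert m.predict([[0.0]])[0] == pytest.approx(87.0, abs=1e-9)

    def test_zero_noise_interpolates_training_targets(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-1, 1, size=(40, 3))
        y = 100 + 10 * X[:, 0] - 5 * X[:, 1] ** 2
        m = gpr.GaussianProcessBP("exponential", 0.5, noise_level=0.0,
                                  standardize=False).fit(X, y)
        assert np.max(np.abs(m.predict(X) - y)) < 1e-6

    def test_far_prediction_reverts_to_prior_mean(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, size=(30, 2))
        y = rng.uniform(70, 90, size=30)
        m = gpr.GaussianProcessBP("matern52", 0.3, standardize=False).fit(X, y)
        far = m.predict([[50.0, -60.0]])[0]
        assert far == pytest.approx(y.mean(), abs=1e-6)

    def test_predictive_std_nonnegative_and_zero_at_training_points(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([80.0, 85.0, 90.0])
        m = gpr.GaussianProcessBP("matern52", 0.5, noise_level=0.0,
                                  standardize=False).fit(X, y)
        est, std = m.predict(np.vstack([X, [[0.5]]]), return_std=True)
        assert np.all(std >= 0)
        assert np.all(std[:3] < 1e-4) and std[3] > 1e-3

    def test_monotone_relationship_is_preserved(self):
        X = np.linspace(0, 1, 60).reshape(-1, 1)
        y = 70 + 30 * X[:, 0]
        m = gpr.GaussianProcessBP("matern52", 0.3).fit(X, y)
        grid = np.linspace(0.02, 0.98, 25).reshape(-1, 1)
        pred = m.predict(grid)
        assert np.all(np.diff(pred) > 0)

    def test_empty_prediction_set(self):
        m = gpr.GaussianProcessBP("rbf", 0.2, standardize=False).fit(
            [[0.0], [1.0]], [70.0, 80.0])
        assert m.predict(np.empty((0, 1))).size == 0

    def test_conflicting_duplicates_with_zero_noise_raise(self):
        with pytest.raises(IllConditionedError):
            gpr.GaussianProcessBP("rbf", 0.5, noise_level=0.0,
                                  standardize=False).fit(
                [[0.0], [0.0]], [70.0, 90.0])

    def test_schema_mismatch_on_predict(self):
        m = gpr.GaussianProcessBP("rbf", 0.2, standardize=False).fit(
            [[0.0, 1.0]], [70.0])
        with pytest.raises(SchemaError):
            m.predict([[0.0]])


class TestTuneSigma:
    def test_selection_is_predictively_optimal_on_gp_data(self):
        """On data simulated from a known GP the tuner returns the grid
        minimizer of CV RMSE; the generating length-scale is predictively
        competitive (CV selection optimizes prediction, not identification,
        so the minimizer may sit above the generating value) and a
        drastically under-smoothed sigma is never preferred."""
        rng = np.random.default_rng(5)
        n, sigma_true, noise_sd = 40, 0.15, 0.05
        X = rng.uniform(0, 1, size=(n, 1))
        K = gpr.kernel_matrix("matern52", sigma_true, X) + 1e-10 * np.eye(n)
        y = np.linalg.cholesky(K) @ rng.normal(size=n) + rng.normal(0, noise_sd, n)
        grid = np.linspace(0.01, 0.5, 13)
        cfgk, table = gpr.tune_sigma(X, y, "matern52", grid=grid, rng_seed=5,
                                     noise_level=noise_sd ** 2, input_std=1.0)
        rmse = table.set_index("sigma")["cv_rmse"]
        assert rmse[cfgk.sigma] == rmse.min()
        assert cfgk.sigma >= 0.5 * sigma_true  # never grossly under-smooths
        assert rmse.iloc[0] > rmse[cfgk.sigma]  # sigma=0.01 under-smooths

    def test_pure_noise_has_flat_cv_profile_near_target_sd(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, size=(80, 3))
        y = rng.normal(0.0, 2.0, size=80)
        _, table = gpr.tune_sigma(X, y, "exponential", grid=[0.05, 0.2, 0.5],
                                  rng_seed=6, noise_level=1e-4, input_std=1.0)
        assert np.all(table["cv_rmse"] > 0.7 * 2.0)
        assert np.all(table["cv_rmse"] < 1.6 * 2.0)

    def test_seeded_selection_is_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(40, 2))
        y = rng.normal(size=40)
        a, _ = gpr.tune_sigma(X, y, "matern52", grid=[0.1, 0.2, 0.3], rng_seed=3)
        b, _ = gpr.tune_sigma(X, y, "matern52", grid=[0.1, 0.2, 0.3], rng_seed=3)
        assert a.sigma == b.sigma

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gpr.tune_sigma(np.zeros((20, 1)), np.zeros(20), "rbf", grid=[])


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = gpr.evaluate([70.0, 80.0, 90.0], [70.0, 80.0, 90.0])
        assert rep.mean_error == 0 and rep.rmse == 0 and rep.mae == 0
        assert rep.r_squared == pytest.approx(1.0)

    def test_hand_computed_residuals(self):
        rep = gpr.evaluate([81.0, 79.0], [80.0, 80.0])
        assert rep.mean_error == pytest.approx(0.0)
        assert rep.rmse == pytest.approx(1.0)
        assert rep.mae == pytest.approx(1.0)

    def test_rmse_decomposition_identity(self):
        rng = np.random.default_rng(8)
        est, ref = rng.normal(size=50), rng.normal(size=50)
        rep = gpr.evaluate(est, ref)
        resid = est - ref
        assert rep.rmse ** 2 == pytest.approx(
            rep.mean_error ** 2 + np.var(resid), rel=1e-12)

    def test_zero_variance_references_have_no_r_squared(self):
        rep = gpr.evaluate([70.0, 71.0], [75.0, 75.0])
        assert rep.r_squared is None

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(2, 60)
            est, ref = rng.normal(100, 10, n), rng.normal(100, 10, n)
            rep = gpr.evaluate(est, ref)
            r = [e - f for e, f in zip(est, ref)]
            assert rep.mean_error == pytest.approx(sum(r) / n, rel=1e-12, abs=1e-12)
            assert rep.rmse == pytest.approx((sum(v * v for v in r) / n) ** 0.5,
                                             rel=1e-12)
            assert rep.mae == pytest.approx(sum(abs(v) for v in r) / n, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gpr.evaluate([1.0, 2.0], [1.0])
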