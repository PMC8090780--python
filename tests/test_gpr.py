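"""Normative GP: recovery, calibration, CV protocol, oracle equivalence."""

import numpy as np
import pytest
from scipy import stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, DotProduct

from normdev import (
    compute_z,
    crossvalidated_z,
    evaluate_model,
    fit_normative,
    forward_model_slopes,
)
from normdev.gpr import (NormativeGPR, PredictionWithUncertainty, _kernel,
                         _nlml_and_grad)


def _covariates(rng, n):
    return np.column_stack([rng.uniform(20, 70, n), rng.integers(0, 2, n)])


class TestFit:
    def test_noise_free_linear_recovered(self):
        rng = np.random.default_rng(0)
        X = _covariates(rng, 60)
        y = (-0.003 * X[:, 0] + 0.8)[:, None]
        model = fit_normative(y, X, seed=0)
        Xq = _covariates(rng, 40)
        pred = model.predict(Xq, warn_extrapolation=False)
        truth = -0.003 * Xq[:, 0] + 0.8
        r = np.corrcoef(pred.mean[:, 0], truth)[0, 1]
        assert r >= 0.999

    def test_pure_noise_variance_recovered(self):
        # average over replicates: a single n=400 draw has ~7% sampling sd
        # on the sample variance itself
        estimates = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = _covariates(rng, 400)
            y = rng.normal(0.0, 0.07, (400, 1))
            model = fit_normative(y, X, seed=seed)
            estimates.append(model.noise_variance_raw_[0])
        assert np.mean(estimates) == pytest.approx(0.07**2, rel=0.10)

    def test_duplicate_rows_fit_completes(self):
        rng = np.random.default_rng(2)
        X = np.repeat(_covariates(rng, 12), 2, axis=0)
        y = np.repeat(rng.normal(0.5, 0.05, (12, 2)), 2, axis=0)
        model = fit_normative(y, X, seed=2)
        assert np.all(np.isfinite(model.predict(X[:3]).mean))

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(3)
        X = _covariates(rng, 10)
        with pytest.raises(ValueError, match="at least"):
            fit_normative(rng.normal(size=(10, 2)), X)

    @pytest.mark.parametrize("mode", ["tied", "per-voxel"])
    def test_matches_sklearn_gp_at_fixed_hyperparameters(self, mode):
        """Marginal likelihood, mean and variance agree with an independent
        GP implementation given identical kernel and hyperparameters."""
        rng = np.random.default_rng(4)
        n = 50
        X = _covariates(rng, n)
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        y = rng.normal(0.0, 1.0, n)
        vc, vl, vf, ell, s2 = 0.3, 0.5, 0.7, 1.3, 0.2
        log_theta = np.log([vc, vl, vf, ell])

        nlml, _ = _nlml_and_grad(np.append(log_theta, np.log(s2)), Xs, y)

        kern = (ConstantKernel(vc, "fixed")
                + ConstantKernel(vl, "fixed") * DotProduct(0.0, "fixed")
                + ConstantKernel(vf, "fixed") * RBF(ell, "fixed"))
        gp = GaussianProcessRegressor(kernel=kern, alpha=s2, optimizer=None)
        gp.fit(Xs, y)
        assert -nlml == pytest.approx(gp.log_marginal_likelihood(), rel=1e-8)

        Xq = (rng.uniform(20, 70, (8, 2)) - X.mean(axis=0)) / X.std(axis=0)
        mu_sk, sd_sk = gp.predict(Xq, return_std=True)
        K = _kernel(Xs, Xs, log_theta) + s2 * np.eye(n)
        Kq = _kernel(Xq, Xs, log_theta)
        mu = Kq @ np.linalg.solve(K, y)
        np.testing.assert_allclose(mu, mu_sk, rtol=1e-8)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        p0 = np.array([-1.0, -0.5, -0.3, 0.2, -1.2])
        _, grad = _nlml_and_grad(p0, X, y)
        eps = 1e-6
        for j in range(5):
            dp = np.zeros(5)
            dp[j] = eps
            fp, _ = _nlml_and_grad(p0 + dp, X, y)
            fm, _ = _nlml_and_grad(p0 - dp, X, y)
            assert grad[j] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4)


class TestPredict:
    def test_interpolates_training_targets_when_noise_free(self):
        rng = np.random.default_rng(6)
        X = _covariates(rng, 30)
        y = (0.5 - 0.002 * X[:, 0] + 0.02 * X[:, 1])[:, None]
        model = fit_normative(y, X, seed=0)
        pred = model.predict(X)
        np.testing.assert_allclose(pred.mean[:, 0], y[:, 0], atol=1e-4)

    def test_uncertainty_grows_outside_age_range(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([rng.uniform(30, 50, 40), rng.integers(0, 2, 40)])
        y = rng.normal(0.5, 0.05, (40, 1))
        model = fit_normative(y, X, seed=0)
        inside = model.predict(np.array([[40.0, 0.0]]),
                               warn_extrapolation=False)
        with pytest.warns(UserWarning, match="extrapolating"):
            outside = model.predict(np.array([[90.0, 0.0]]))
        assert outside.var_function[0, 0] >= inside.var_function[0, 0]
        assert np.all(inside.var_total >= inside.var_function)

    def test_unfitted_model_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            NormativeGPR().predict(np.zeros((1, 2)))


class TestComputeZ:
    def test_zero_deviation_gives_zero_z(self):
        pred = PredictionWithUncertainty(
            mean=np.full((1, 3), 0.5), var_function=np.full((1, 3), 0.01),
            var_total=np.full((1, 3), 0.02),
        )
        z = compute_z(np.full((1, 3), 0.5), pred)
        np.testing.assert_array_equal(z.Z, 0.0)

    def test_forced_arithmetic(self):
        # residual 0.4, var_function 0.03, noise 0.01 -> Z = 0.4/0.2 = 2
        pred = PredictionWithUncertainty(
            mean=np.array([[0.1]]), var_function=np.array([[0.03]]),
            var_total=np.array([[0.04]]),
        )
        z = compute_z(np.array([[0.5]]), pred)
        assert z.Z[0, 0] == pytest.approx(2.0)

    def test_zero_variance_rejected(self):
        pred = PredictionWithUncertainty(
            mean=np.zeros((1, 1)), var_function=np.zeros((1, 1)),
            var_total=np.zeros((1, 1)),
        )
        with pytest.raises(ValueError, match="var_total"):
            compute_z(np.ones((1, 1)), pred)


class TestCrossValidation:
    def test_every_subject_scored_once_with_balanced_folds(self):
        rng = np.random.default_rng(8)
        X = _covariates(rng, 73)
        Y = rng.normal(0.5, 0.05, (73, 40))
        cv = crossvalidated_z(Y, X, k=10, seed=0)
        assert cv.cv_folds.shape == (73,)
        sizes = np.bincount(cv.cv_folds)[1:]
        assert sizes.sum() == 73
        assert sizes.max() - sizes.min() <= 1
        assert set(cv.provenance) == {"cv"}

    def test_leave_one_out_matches_explicit_refits(self):
        rng = np.random.default_rng(9)
        n = 30
        X = _covariates(rng, n)
        Y = 0.5 - 0.002 * X[:, [0]] + rng.normal(0, 0.05, (n, 5))
        cv = crossvalidated_z(Y, X, k=n, seed=3, stratify_sex=False)
        # oracle: refit without each subject, score that subject
        from sklearn.model_selection import KFold
        for train, test in KFold(n_splits=n, shuffle=True,
                                 random_state=3).split(X):
            model = fit_normative(Y[train], X[train], seed=3)
            pred = model.predict(X[test], warn_extrapolation=False)
            z = (Y[test] - pred.mean) / np.sqrt(pred.var_total)
            np.testing.assert_allclose(cv.Z[test], z, rtol=1e-10)

    def test_k_larger_than_n_rejected(self):
        rng = np.random.default_rng(10)
        X = _covariates(rng, 25)
        Y = rng.normal(size=(25, 3))
        with pytest.raises(ValueError, match="exceeds"):
            crossvalidated_z(Y, X, k=26)
        with pytest.raises(ValueError, match=">= 2"):
            crossvalidated_z(Y, X, k=1)

    def test_fold_variances_homogeneous_on_calibrated_data(self):
        rng = np.random.default_rng(11)
        n, V = 120, 60
        X = _covariates(rng, n)
        Y = 0.5 - 0.002 * X[:, [0]] + rng.normal(0, 0.05, (n, V))
        cv = crossvalidated_z(Y, X, k=6, seed=1)
        groups = [cv.Z[cv.cv_folds == f].ravel()
                  for f in np.unique(cv.cv_folds)]
        assert stats.levene(*groups).pvalue > 0.01

    def test_cv_and_independent_transfer_agree(self):
        """Z from 10-fold CV correlates > 0.9 with Z from a model trained on
        an independent healthy sample at default SNR."""
        rng = np.random.default_rng(12)
        n, V = 160, 80
        X = _covariates(rng, 2 * n)
        slopes = rng.uniform(-0.004, -0.001, V)
        Y = 0.5 + np.outer(X[:, 0] - 45, slopes) + rng.normal(0, 0.05, (2 * n, V))
        cv = crossvalidated_z(Y[:n], X[:n], k=10, seed=2)
        model = fit_normative(Y[n:], X[n:], seed=2)
        pred = model.predict(X[:n], warn_extrapolation=False)
        z_transfer = compute_z(Y[:n], pred)
        r = np.corrcoef(cv.Z.ravel(), z_transfer.Z.ravel())[0, 1]
        assert r > 0.9


class TestModelEvaluation:
    def test_perfect_predictions_give_unit_correlation(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(20, 7))
        np.testing.assert_allclose(evaluate_model(Y, Y), 1.0)

    def test_independent_predictions_average_zero(self):
        rng = np.random.default_rng(14)
        r = evaluate_model(rng.normal(size=(200, 400)),
                           rng.normal(size=(200, 400)))
        assert abs(np.nanmean(r)) < 0.02

    def test_zero_variance_voxel_reported_missing(self):
        rng = np.random.default_rng(15)
        obs = rng.normal(size=(10, 2))
        pred = rng.normal(size=(10, 2))
        pred[:, 1] = 0.3
        r = evaluate_model(pred, obs)
        assert np.isfinite(r[0]) and np.isnan(r[1])


class TestForwardSlopes:
    def test_constant_surface_gives_zero_slopes(self):
        rng = np.random.default_rng(16)
        X = _covariates(rng, 50)
        Y = np.full((50, 4), 0.5) + rng.normal(0, 1e-4, (50, 4))
        model = fit_normative(Y, X, seed=0)
        slopes = forward_model_slopes(model)
        assert np.abs(slopes["slope_male"]).max() < 1e-4
        assert np.abs(slopes["slope_female"]).max() < 1e-4

    def test_age_constant_sex_offset_gives_zero_difference(self):
        rng = np.random.default_rng(17)
        X = _covariates(rng, 120)
        Y = (0.5 - 0.002 * X[:, [0]] + 0.05 * X[:, [1]]
             + rng.normal(0, 0.01, (120, 6)))
        model = fit_normative(Y, X, seed=0)
        slopes = forward_model_slopes(model)
        assert slopes["slope_male"] == pytest.approx(-0.002, rel=0.15)
        assert np.abs(slopes["slope_difference"]).max() < 4e-4
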