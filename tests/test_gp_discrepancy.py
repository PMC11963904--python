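"""Tests for the constrained-GP discrepancy model.

The key checks are oracle equivalences: kernel derivative blocks against
central finite differences, and posterior conditioning against an
independent dense joint-Gaussian implementation.
"""

import numpy as np
import pytest
from scipy.linalg import solve
from scipy.stats import invgamma

from odclearn import gp_discrepancy as gp
from odclearn.sa_model import sa_predict_matrix


@pytest.fixture()
def hp():
    return gp.GPHyperparams(
        sigma2=0.7, gamma=np.array([1.2, 0.8, 2.0, 1.5, 0.5]), sigma_e2=0.01
    )


def dense_predict(model, X_new):
    """Independent single-solve implementation of the joint conditioning."""
    h = model.hyperparams
    j = model.constraints.deriv_coord
    Xd = model.standardizer(model.X_train)
    Xv = model.standardizer(model.constraints.value_points)
    Xg = model.standardizer(model.constraints.deriv_points)
    K = np.block(
        [
            [
                gp.se_kernel(Xd, Xd, h) + h.sigma_e2 * np.eye(len(Xd)),
                gp.se_kernel(Xd, Xv, h),
                gp.cross_cov_value_deriv(Xd, Xg, h, j),
            ],
            [
                gp.se_kernel(Xv, Xd, h),
                gp.se_kernel(Xv, Xv, h),
                gp.cross_cov_value_deriv(Xv, Xg, h, j),
            ],
            [
                gp.cross_cov_value_deriv(Xd, Xg, h, j).T,
                gp.cross_cov_value_deriv(Xv, Xg, h, j).T,
                gp.cross_cov_deriv_deriv(Xg, Xg, h, j, j),
            ],
        ]
    )
    obs = np.concatenate([model.residuals, np.zeros(len(Xv) + len(Xg))])
    Xs = model.standardizer(np.atleast_2d(X_new))
    ks = np.hstack(
        [
            gp.se_kernel(Xs, Xd, h),
            gp.se_kernel(Xs, Xv, h),
            gp.cross_cov_value_deriv(Xs, Xg, h, j),
        ]
    )
    mu = ks @ solve(K, obs)
    var = h.sigma2 - np.sum(ks * solve(K, ks.T).T, axis=1)
    return mu, np.sqrt(np.maximum(var, 0.0))


def toy_inputs(rng, n):
    return rng.uniform(-1, 1, size=(n, 5)) * [0.2, 2.0, 0.008, 1.5, 4.0] + [
        7.4, 5.33, 0.01, 37.0, 7.0,
    ]


class TestKernel:
    def test_diagonal_is_variance(self, hp):
        x = np.array([[7.4, 5.0, 0.0, 37.0, 8.0]])
        assert gp.se_kernel(x, x, hp)[0, 0] == pytest.approx(hp.sigma2, abs=1e-15)

    def test_one_length_scale_apart(self, hp):
        x = np.zeros((1, 5))
        y = np.zeros((1, 5))
        y[0, 2] = hp.gamma[2]
        assert gp.se_kernel(x, y, hp)[0, 0] == pytest.approx(
            hp.sigma2 * np.exp(-1.0), rel=1e-12
        )

    def test_symmetry(self, hp, rng):
        A = rng.normal(size=(4, 5))
        np.testing.assert_allclose(
            gp.se_kernel(A, A, hp), gp.se_kernel(A, A, hp).T, atol=1e-15
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            gp.GPHyperparams(sigma2=1.0, gamma=np.array([1, 1, 0, 1, 1.0]), sigma_e2=0.1)


class TestDerivativeBlocks:
    def test_value_deriv_vanishes_at_coincidence(self, hp):
        x = np.ones((1, 5))
        assert gp.cross_cov_value_deriv(x, x, hp, 4)[0, 0] == 0.0

    def test_deriv_deriv_diagonal(self, hp):
        x = np.ones((1, 5))
        for j in range(5):
            assert gp.cross_cov_deriv_deriv(x, x, hp, j, j)[0, 0] == pytest.approx(
                2 * hp.sigma2 / hp.gamma[j] ** 2, rel=1e-12
            )

    def test_finite_difference_oracle(self, hp, rng):
        x = rng.normal(size=(1, 5))
        y = rng.normal(size=(1, 5))
        h = 1e-5
        for j in range(5):
            e = np.eye(5)[j]
            num = (gp.se_kernel(x, y + h * e, hp) - gp.se_kernel(x, y - h * e, hp)) / (2 * h)
            assert gp.cross_cov_value_deriv(x, y, hp, j)[0, 0] == pytest.approx(
                num[0, 0], abs=1e-6
            )
            num2 = (
                gp.cross_cov_value_deriv(x + h * e, y, hp, j)
                - gp.cross_cov_value_deriv(x - h * e, y, hp, j)
            ) / (2 * h)
            assert gp.cross_cov_deriv_deriv(x, y, hp, j, j)[0, 0] == pytest.approx(
                -num2[0, 0], abs=1e-6
            )


class TestPriors:
    def test_inverse_gamma_solution(self):
        # mean 0.09, mode 0.04 => shape 2.6, scale 0.144
        shape, scale = gp._invgamma_from_mean_mode(0.09, 0.04)
        assert shape == pytest.approx(2.6, abs=1e-12)
        assert scale == pytest.approx(0.144, abs=1e-12)

    def test_tail_monotonicity(self):
        priors = gp.GPPriors()
        base = gp.GPHyperparams(sigma2=0.09, gamma=np.full(5, 2.0), sigma_e2=0.016**2)
        absurd = gp.GPHyperparams(sigma2=0.09, gamma=np.array([2, 2, 2, 2, 1e6]), sigma_e2=0.016**2)
        assert priors.log_density(absurd) < priors.log_density(base)

    def test_log_posterior_additivity(self, rng):
        X = toy_inputs(rng, 5)
        z = sa_predict_matrix(X, a4_override=-0.4)
        resid = z - sa_predict_matrix(X, a4_override=0.0)
        constraints = gp.default_constraints()
        priors = gp.GPPriors()
        hp = gp.GPHyperparams(sigma2=0.09, gamma=np.full(5, 2.0), sigma_e2=1e-4)
        lp = gp.log_posterior(hp, X, resid, constraints, priors)
        # recompute the two parts independently
        std = gp._Standardizer.fit(X)
        Xd, Xv, Xg = std(X), std(constraints.value_points), std(constraints.deriv_points)
        K = gp._joint_cov(hp, Xd, Xv, Xg, 4)
        obs = np.concatenate([resid, np.zeros(4)])
        sign, logdet = np.linalg.slogdet(K)
        loglik = -0.5 * (obs @ np.linalg.solve(K, obs) + logdet + len(obs) * np.log(2 * np.pi))
        assert lp == pytest.approx(loglik + priors.log_density(hp), abs=1e-8)


class TestConditioning:
    def test_dense_oracle_equivalence(self, rng):
        X = toy_inputs(rng, 8)
        z = sa_predict_matrix(X, a4_override=-0.5) + 0.01 * rng.normal(size=8)
        model = gp.map_fit(X, z, n_starts=2, seed=0, maxiter=40)
        X_new = toy_inputs(rng, 6)
        pred = gp.predict(model, X_new)
        mu, sd = dense_predict(model, X_new)
        np.testing.assert_allclose(pred.delta_mean, mu, atol=1e-8)
        np.testing.assert_allclose(pred.sd, sd, atol=1e-8)

    def test_constraint_satisfaction(self, rng):
        X = toy_inputs(rng, 20)
        z = sa_predict_matrix(X, a4_override=-0.6) + 0.02 * rng.normal(size=20)
        model = gp.map_fit(X, z, n_starts=3, seed=1, maxiter=60)
        at_value = gp.predict(model, model.constraints.value_points)
        assert np.max(np.abs(at_value.delta_mean)) < 1e-6
        assert np.max(at_value.sd) < 1e-4

    def test_prior_reversion_without_data(self, rng):
        hp = gp.GPHyperparams(sigma2=0.25, gamma=np.full(5, 1.0), sigma_e2=1e-4)
        std = gp._Standardizer(mean=np.zeros(5), scale=np.ones(5))
        model = gp.GPDiscrepancyModel(
            hyperparams=hp,
            constraints=gp.ConstraintSet(
                value_points=np.zeros((0, 5)), deriv_points=np.zeros((0, 5))
            ),
            X_train=np.zeros((0, 5)),
            residuals=np.zeros(0),
            standardizer=std,
        )
        model.factorize()
        X_new = np.array([[7.4, 5.33, 0.0, 37.0, 7.0]])
        pred = gp.predict(model, X_new)
        f = sa_predict_matrix(X_new, a4_override=0.0)
        assert pred.mean[0] == pytest.approx(f[0], abs=1e-12)
        assert pred.sd[0] == pytest.approx(np.sqrt(hp.sigma2), abs=1e-12)

    def test_interpolation_as_noise_vanishes(self, rng):
        X = toy_inputs(rng, 10)
        z = sa_predict_matrix(X, a4_override=-0.45)
        resid = z - sa_predict_matrix(X, a4_override=0.0)
        hp = gp.GPHyperparams(sigma2=0.09, gamma=np.full(5, 2.0), sigma_e2=1e-12)
        model = gp.GPDiscrepancyModel(
            hyperparams=hp,
            constraints=gp.default_constraints(),
            X_train=X,
            residuals=resid,
            standardizer=gp._Standardizer.fit(X),
        )
        model.factorize()
        pred = gp.predict(model, X)
        np.testing.assert_allclose(pred.delta_mean, resid, atol=1e-5)


class TestMapFit:
    def test_determinism(self, rng):
        X = toy_inputs(rng, 15)
        z = sa_predict_matrix(X, a4_override=-0.5) + 0.01 * rng.normal(size=15)
        m1 = gp.map_fit(X, z, n_starts=2, seed=5, maxiter=40)
        m2 = gp.map_fit(X, z, n_starts=2, seed=5, maxiter=40)
        assert m1.hyperparams.sigma2 == m2.hyperparams.sigma2
        np.testing.assert_array_equal(m1.hyperparams.gamma, m2.hyperparams.gamma)

    def test_optimum_beats_starts(self, rng):
        X = toy_inputs(rng, 15)
        z = sa_predict_matrix(X, a4_override=-0.5) + 0.01 * rng.normal(size=15)
        constraints = gp.default_constraints()
        priors = gp.GPPriors()
        model = gp.map_fit(X, z, constraints=constraints, priors=priors, n_starts=3, seed=2, maxiter=60)
        resid = model.residuals
        lp_opt = gp.log_posterior(
            model.hyperparams, X, resid, constraints, priors, standardizer=model.standardizer
        )
        start_rng = np.random.default_rng(2)
        for _ in range(3):
            hp0 = priors.sample(start_rng)
            assert lp_opt >= gp.log_posterior(
                hp0, X, resid, constraints, priors, standardizer=model.standardizer
            ) - 1e-9

    def test_hyperparameter_recovery_from_gp_data(self):
        # data simulated from a GP with known hyperparameters: MAP estimates
        # should land within broad log-scale tolerance
        rng = np.random.default_rng(7)
        true = gp.GPHyperparams(sigma2=0.09, gamma=np.array([4, 4, 4, 4, 1.0]), sigma_e2=2.5e-4)
        X = toy_inputs(rng, 100)
        std = gp._Standardizer.fit(X)
        K = gp.se_kernel(std(X), std(X), true) + 1e-10 * np.eye(100)
        delta = np.linalg.cholesky(K) @ rng.normal(size=100)
        z = sa_predict_matrix(X, a4_override=0.0) + delta + np.sqrt(true.sigma_e2) * rng.normal(size=100)
        model = gp.map_fit(X, z, n_starts=4, seed=7, maxiter=80)
        assert abs(np.log(model.hyperparams.sigma2) - np.log(true.sigma2)) < 1.0

    def test_calibration_on_gp_draws(self):
        # draw a discrepancy from the prior GP, condition on noisy values,
        # check ~95% coverage of held-out noiseless values at +/- 2 SD
        rng = np.random.default_rng(42)
        hp = gp.GPHyperparams(sigma2=0.04, gamma=np.array([3, 3, 3, 3, 0.8]), sigma_e2=1e-4)
        X = toy_inputs(rng, 120)
        std = gp._Standardizer.fit(X)
        K = gp.se_kernel(std(X), std(X), hp) + 1e-10 * np.eye(120)
        delta = np.linalg.cholesky(K) @ rng.normal(size=120)
        f = sa_predict_matrix(X, a4_override=0.0)
        z = f + delta + np.sqrt(hp.sigma_e2) * rng.normal(size=120)
        train, test = np.arange(70), np.arange(70, 120)
        model = gp.GPDiscrepancyModel(
            hyperparams=hp,
            constraints=gp.ConstraintSet(np.zeros((0, 5)), np.zeros((0, 5))),
            X_train=X[train],
            residuals=(z - f)[train],
            standardizer=std,
        )
        model.factorize()
        pred = gp.predict(model, X[test])
        inside = np.abs(delta[test] - pred.delta_mean) <= 2 * pred.sd
        # binomial(50, 0.95): >= 42 successes covers ~4 sigma
        assert inside.sum() >= 42
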