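"""Additive Gaussian-process model discrepancy for the dissociation curve.

Black-box correction of the mechanistic model: observations are modelled as

    z = f(x) + delta(x) + e,        e ~ N(0, sigma_e^2),

where ``f`` is the baseline model with a4 = 0 and ``delta`` is a zero-mean GP
with separable squared-exponential kernel

    k(x, x') = sigma^2 * exp( - sum_i ((x_i - x_i') / gamma_i)^2 ).

Clinical prior knowledge — that the discrepancy vanishes, flatly, at the
extremes of the pressure range where the curve saturates — enters as exact
(noise-free) observations of delta and of its derivative along the p
coordinate.  Hyperparameters (sigma^2, gamma, sigma_e^2) are estimated by
maximum a posteriori with multi-start L-BFGS on the log scale.

Inputs are standardized per coordinate before kernel evaluation; the Gamma
priors on the correlation lengths are interpreted on that standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .sa_model import CONSTANTS, sa_predict_matrix

__all__ = [
    "GPHyperparams",
    "GPPriors",
    "ConstraintSet",
    "GPDiscrepancyModel",
    "GPPrediction",
    "se_kernel",
    "cross_cov_value_deriv",
    "cross_cov_deriv_deriv",
    "default_constraints",
    "log_posterior",
    "map_fit",
    "predict",
]

#: index of the combined-pressure coordinate in the (pH, PCO2, FMetHb, T, p) layout
P_COORD = 4


@dataclass(frozen=True)
class GPHyperparams:
    """Kernel variance, per-coordinate correlation lengths, noise variance."""

    sigma2: float
    gamma: np.ndarray          # shape (d,), standardized-input units
    sigma_e2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gamma", np.asarray(self.gamma, dtype=float))
        if self.sigma2 <= 0 or self.sigma_e2 <= 0 or np.any(self.gamma <= 0):
            raise ValueError("all hyperparameters must be strictly positive")

    def to_log_vector(self) -> np.ndarray:
        return np.log(np.concatenate([[self.sigma2], self.gamma, [self.sigma_e2]]))

    @classmethod
    def from_log_vector(cls, v: np.ndarray, fixed_sigma_e2: Optional[float] = None):
        v = np.asarray(v, dtype=float)
        if fixed_sigma_e2 is not None:
            return cls(sigma2=np.exp(v[0]), gamma=np.exp(v[1:6]), sigma_e2=fixed_sigma_e2)
        return cls(sigma2=np.exp(v[0]), gamma=np.exp(v[1:6]), sigma_e2=np.exp(v[6]))


def _invgamma_from_mean_mode(mean: float, mode: float) -> Tuple[float, float]:
    """Shape/scale of an Inverse-Gamma with the given mean and mode.

    mean = scale/(shape-1), mode = scale/(shape+1)  =>
    shape = (mean+mode)/(mean-mode), scale = mean*(shape-1).
    """
    if not 0 < mode < mean:
        raise ValueError("need 0 < mode < mean for a proper Inverse-Gamma")
    shape = (mean + mode) / (mean - mode)
    scale = mean * (shape - 1.0)
    # sanity: round-trip the moments
    assert abs(scale / (shape - 1.0) - mean) < 1e-12
    assert abs(scale / (shape + 1.0) - mode) < 1e-12
    return shape, scale


@dataclass(frozen=True)
class GPPriors:
    """MAP priors: Inverse-Gamma on the variances, Gamma (shape-rate) on lengths.

    Defaults: sigma^2 ~ InvGamma with mean 0.3^2 and mode 0.2^2 (shape 2.6,
    scale 0.144); sigma_e^2 ~ InvGamma with mean 0.016^2 and mode 0.015^2;
    correlation lengths Gamma(42, 9) for the four slowly acting inputs and a
    tighter Gamma(4, 4) along p, where the discrepancy varies fastest.
    """

    sigma2_mean: float = 0.3**2
    sigma2_mode: float = 0.2**2
    sigma_e2_mean: float = 0.016**2
    sigma_e2_mode: float = 0.015**2
    gamma_shape: float = 42.0
    gamma_rate: float = 9.0
    gamma_p_shape: float = 4.0
    gamma_p_rate: float = 4.0

    def _dists(self):
        a_s, th_s = _invgamma_from_mean_mode(self.sigma2_mean, self.sigma2_mode)
        a_e, th_e = _invgamma_from_mean_mode(self.sigma_e2_mean, self.sigma_e2_mode)
        d_sigma2 = stats.invgamma(a_s, scale=th_s)
        d_sigma_e2 = stats.invgamma(a_e, scale=th_e)
        d_gamma = stats.gamma(self.gamma_shape, scale=1.0 / self.gamma_rate)
        d_gamma_p = stats.gamma(self.gamma_p_shape, scale=1.0 / self.gamma_p_rate)
        return d_sigma2, d_sigma_e2, d_gamma, d_gamma_p

    def log_density(self, hp: GPHyperparams, include_sigma_e2: bool = True) -> float:
        d_sigma2, d_sigma_e2, d_gamma, d_gamma_p = self._dists()
        lp = d_sigma2.logpdf(hp.sigma2)
        for i, g in enumerate(hp.gamma):
            lp += (d_gamma_p if i == P_COORD else d_gamma).logpdf(g)
        if include_sigma_e2:
            lp += d_sigma_e2.logpdf(hp.sigma_e2)
        return float(lp)

    def sample(self, rng: np.random.Generator, d: int = 5) -> GPHyperparams:
        d_sigma2, d_sigma_e2, d_gamma, d_gamma_p = self._dists()
        gamma = np.array(
            [
                (d_gamma_p if i == P_COORD else d_gamma).rvs(random_state=rng)
                for i in range(d)
            ]
        )
        return GPHyperparams(
            sigma2=float(d_sigma2.rvs(random_state=rng)),
            gamma=gamma,
            sigma_e2=float(d_sigma_e2.rvs(random_state=rng)),
        )


@dataclass(frozen=True)
class ConstraintSet:
    """Noise-free constraints: delta = 0 at ``value_points`` and
    d delta / d x_p = 0 at ``deriv_points`` (raw, unstandardized inputs)."""

    value_points: np.ndarray   # (m, 5)
    deriv_points: np.ndarray   # (k, 5)
    deriv_coord: int = P_COORD

    def __post_init__(self) -> None:
        object.__setattr__(self, "value_points", np.atleast_2d(np.asarray(self.value_points, float)))
        object.__setattr__(self, "deriv_points", np.atleast_2d(np.asarray(self.deriv_points, float)))
        if not (0 <= self.deriv_coord < 5):
            raise ValueError("deriv_coord must index one of the 5 inputs")

    @property
    def n_constraints(self) -> int:
        return len(self.value_points) + len(self.deriv_points)


def default_constraints(p_low: float = 0.5, p_high: float = 45.0) -> ConstraintSet:
    """Value + derivative constraints at extreme pressures, other inputs at reference."""
    base = np.array([CONSTANTS.pH_ref, CONSTANTS.PCO2_ref, 0.0, CONSTANTS.T_ref, 0.0])
    pts = np.vstack([base, base])
    pts[0, P_COORD] = p_low
    pts[1, P_COORD] = p_high
    return ConstraintSet(value_points=pts, deriv_points=pts.copy())


def _sq_scaled_dists(A: np.ndarray, B: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    diff = A[:, None, :] - B[None, :, :]
    return np.sum((diff / gamma) ** 2, axis=-1), diff


def se_kernel(A, B, hp: GPHyperparams) -> np.ndarray:
    """Squared-exponential kernel matrix between row sets A (n,d) and B (m,d)."""
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    if A.shape[1] != B.shape[1] or A.shape[1] != hp.gamma.shape[0]:
        raise ValueError("input dimensions must match the hyperparameter vector")
    r2, _ = _sq_scaled_dists(A, B, hp.gamma)
    return hp.sigma2 * np.exp(-r2)


def cross_cov_value_deriv(A, B, hp: GPHyperparams, deriv_coord: int) -> np.ndarray:
    """cov(delta(a), d delta(b) / d b_j) for rows a of A, b of B.

    Differentiating k(a, b) with respect to b_j gives
    ``k(a, b) * 2 (a_j - b_j) / gamma_j^2``.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    j = deriv_coord
    if not 0 <= j < hp.gamma.shape[0]:
        raise ValueError("invalid derivative coordinate")
    r2, diff = _sq_scaled_dists(A, B, hp.gamma)
    return hp.sigma2 * np.exp(-r2) * 2.0 * diff[:, :, j] / hp.gamma[j] ** 2


def cross_cov_deriv_deriv(A, B, hp: GPHyperparams, i: int, j: int) -> np.ndarray:
    """cov(d delta(a)/d a_i, d delta(b)/d b_j).

    Second mixed derivative of the SE kernel:
    ``(2 * 1[i==j] / gamma_j^2 - 4 d_i d_j / (gamma_i^2 gamma_j^2)) * k``
    with d = a - b.
    """
    A = np.atleast_2d(np.asarray(A, float))
    B = np.atleast_2d(np.asarray(B, float))
    g = hp.gamma
    if not (0 <= i < g.shape[0] and 0 <= j < g.shape[0]):
        raise ValueError("invalid derivative coordinate")
    r2, diff = _sq_scaled_dists(A, B, g)
    k = hp.sigma2 * np.exp(-r2)
    term = -4.0 * diff[:, :, i] * diff[:, :, j] / (g[i] ** 2 * g[j] ** 2)
    if i == j:
        term = term + 2.0 / g[j] ** 2
    return k * term


@dataclass
class _Standardizer:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) / self.scale


def _joint_cov(hp: GPHyperparams, Xd, Xv, Xg, deriv_coord: int) -> np.ndarray:
    """Joint covariance over [data obs; value constraints; deriv constraints]."""
    j = deriv_coord
    K_dd = se_kernel(Xd, Xd, hp) + hp.sigma_e2 * np.eye(len(Xd))
    K_dv = se_kernel(Xd, Xv, hp) if len(Xv) else np.zeros((len(Xd), 0))
    K_dg = cross_cov_value_deriv(Xd, Xg, hp, j) if len(Xg) else np.zeros((len(Xd), 0))
    K_vv = se_kernel(Xv, Xv, hp) if len(Xv) else np.zeros((0, 0))
    K_vg = cross_cov_value_deriv(Xv, Xg, hp, j) if (len(Xv) and len(Xg)) else np.zeros((len(Xv), len(Xg)))
    K_gg = cross_cov_deriv_deriv(Xg, Xg, hp, j, j) if len(Xg) else np.zeros((0, 0))
    top = np.hstack([K_dd, K_dv, K_dg])
    mid = np.hstack([K_dv.T, K_vv, K_vg])
    bot = np.hstack([K_dg.T, K_vg.T, K_gg])
    return np.vstack([top, mid, bot])


def _chol_with_jitter(K: np.ndarray, scale: float):
    """Cholesky with an escalating diagonal jitter ladder (1e-10 .. 1e-6) * scale."""
    jitter = 0.0
    for level in [0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6]:
        try:
            jitter = level * scale
            return cho_factor(K + jitter * np.eye(len(K)), lower=True), jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"joint covariance not positive definite after max jitter {jitter:g}"
    )


@dataclass
class GPDiscrepancyModel:
    """Fitted state of the constrained-GP discrepancy model."""

    hyperparams: GPHyperparams
    constraints: ConstraintSet
    X_train: np.ndarray        # raw inputs (n, 5)
    residuals: np.ndarray      # z - f(x) on the training set
    standardizer: _Standardizer
    _cho: object = None
    _alpha: np.ndarray = None
    _obs: np.ndarray = None

    def _blocks(self):
        Xd = self.standardizer(self.X_train)
        Xv = self.standardizer(self.constraints.value_points)
        Xg = self.standardizer(self.constraints.deriv_points)
        return Xd, Xv, Xg

    def factorize(self) -> None:
        Xd, Xv, Xg = self._blocks()
        self._obs = np.concatenate(
            [self.residuals, np.zeros(len(Xv)), np.zeros(len(Xg))]
        )
        if len(self._obs) == 0:
            self._cho = "empty"
            self._alpha = np.zeros(0)
            return
        K = _joint_cov(self.hyperparams, Xd, Xv, Xg, self.constraints.deriv_coord)
        self._cho, _ = _chol_with_jitter(K, self.hyperparams.sigma2)
        self._alpha = cho_solve(self._cho, self._obs)


@dataclass(frozen=True)
class GPPrediction:
    """Updated-model mean f + delta with latent and observation-level SDs."""

    mean: np.ndarray
    delta_mean: np.ndarray
    sd: np.ndarray       # latent (excludes sigma_e2)
    sd_obs: np.ndarray   # includes sigma_e2


def log_posterior(
    hp: GPHyperparams,
    X: np.ndarray,
    residuals: np.ndarray,
    constraints: ConstraintSet,
    priors: GPPriors,
    standardizer: Optional[_Standardizer] = None,
    include_sigma_e2_prior: bool = True,
) -> float:
    """Unnormalized log posterior: joint Gaussian marginal + log priors.

    The marginal is over the data residuals together with the noise-free
    constraint block (zeros), under the joint covariance including the
    value-derivative and derivative-derivative kernel blocks.
    """
    standardizer = standardizer or _Standardizer.fit(np.atleast_2d(X))
    Xd = standardizer(X)
    Xv = standardizer(constraints.value_points)
    Xg = standardizer(constraints.deriv_points)
    K = _joint_cov(hp, Xd, Xv, Xg, constraints.deriv_coord)
    obs = np.concatenate([np.asarray(residuals, float), np.zeros(len(Xv) + len(Xg))])
    cho, _ = _chol_with_jitter(K, hp.sigma2)
    alpha = cho_solve(cho, obs)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    n = len(obs)
    loglik = -0.5 * (obs @ alpha + logdet + n * np.log(2.0 * np.pi))
    return loglik + priors.log_density(hp, include_sigma_e2=include_sigma_e2_prior)


def map_fit(
    X: np.ndarray,
    z: np.ndarray,
    constraints: Optional[ConstraintSet] = None,
    priors: Optional[GPPriors] = None,
    n_starts: int = 8,
    seed: int = 0,
    fix_sigma_e2: Optional[float] = None,
    maxiter: int = 150,
) -> GPDiscrepancyModel:
    """MAP estimation of the GP hyperparameters by multi-start L-BFGS.

    ``z`` are the raw observations; residuals against the a4 = 0 baseline
    are formed internally.  Optimization runs on log-transformed
    hyperparameters with starts drawn from the priors.  ``fix_sigma_e2``
    pins the observation-error variance (clinical mode, where recorded
    saturations are treated as highly accurate).
    """
    X = np.atleast_2d(np.asarray(X, float))
    z = np.asarray(z, float)
    if len(X) < 2:
        raise ValueError("need at least two data points")
    constraints = constraints if constraints is not None else default_constraints()
    priors = priors if priors is not None else GPPriors()
    residuals = z - sa_predict_matrix(X, a4_override=0.0)
    standardizer = _Standardizer.fit(X)
    rng = np.random.default_rng(seed)
    include_e = fix_sigma_e2 is None

    def objective(v: np.ndarray) -> float:
        try:
            hp = GPHyperparams.from_log_vector(v, fixed_sigma_e2=fix_sigma_e2)
            return -log_posterior(
                hp, X, residuals, constraints, priors,
                standardizer=standardizer, include_sigma_e2_prior=include_e,
            )
        except np.linalg.LinAlgError:
            return 1e12

    starts = []
    for _ in range(n_starts):
        hp0 = priors.sample(rng)
        v0 = hp0.to_log_vector()
        starts.append(v0 if include_e else v0[:6])

    best = None
    failures = []
    for v0 in starts:
        res = optimize.minimize(
            objective, v0, method="L-BFGS-B", options={"maxiter": maxiter}
        )
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all optimization starts failed: {failures}")

    hp = GPHyperparams.from_log_vector(best.x, fixed_sigma_e2=fix_sigma_e2)
    model = GPDiscrepancyModel(
        hyperparams=hp,
        constraints=constraints,
        X_train=X,
        residuals=residuals,
        standardizer=standardizer,
    )
    model.factorize()
    return model


def predict(model: GPDiscrepancyModel, X_new: np.ndarray) -> GPPrediction:
    """Posterior of the updated model f + delta at new inputs.

    Standard joint-Gaussian conditioning on the residual data and the
    noise-free constraint block.  The latent SD describes the updated model
    itself; ``sd_obs`` adds the observation-error variance.
    """
    if model._cho is None:
        raise RuntimeError("model is not factorized; call map_fit or factorize() first")
    X_new = np.atleast_2d(np.asarray(X_new, float))
    hp = model.hyperparams
    Xs = model.standardizer(X_new)
    Xd, Xv, Xg = model._blocks()
    j = model.constraints.deriv_coord
    k_star = np.hstack(
        [
            se_kernel(Xs, Xd, hp),
            se_kernel(Xs, Xv, hp) if len(Xv) else np.zeros((len(Xs), 0)),
            cross_cov_value_deriv(Xs, Xg, hp, j) if len(Xg) else np.zeros((len(Xs), 0)),
        ]
    )
    if model._cho == "empty":
        delta_mean = np.zeros(len(Xs))
        var = np.full(len(Xs), hp.sigma2)
    else:
        delta_mean = k_star @ model._alpha
        v = cho_solve(model._cho, k_star.T)
        var = np.maximum(hp.sigma2 - np.sum(k_star * v.T, axis=1), 0.0)
    f = sa_predict_matrix(X_new, a4_override=0.0)
    return GPPrediction(
        mean=f + delta_mean,
        delta_mean=delta_mean,
        sd=np.sqrt(var),
        sd_obs=np.sqrt(var + hp.sigma_e2),
    )
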