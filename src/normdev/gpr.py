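"""Per-voxel Gaussian-process normative model of gray matter on age and sex.

The normative model regresses each voxel's gray-matter volume on (age, sex)
in healthy subjects with a GP whose kernel is

    k(x, x') = v_c + v_l * <x, x'> + v_f * exp(-||x - x'||^2 / (2 l^2))

on z-scored covariates, plus per-voxel Gaussian observation noise s2_n.
Individual deviation is the normative Z-score

    Z = (y - yhat) / sqrt(var_function + s2_n),

i.e. the observed volume referenced to the full predictive distribution of an
observation, not just of the latent mean.

Because every voxel shares the same covariate matrix, the default fit ties
the covariance hyperparameters across voxels (optimised by marginal
likelihood on a seeded voxel subsample and median-pooled in log space) while
the noise variance is optimised exactly per voxel through a single
eigendecomposition of the shared signal kernel.  Full per-voxel optimisation
of all hyperparameters is available with ``hyperparams="per-voxel"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold, KFold

__all__ = [
    "NormativeGPR",
    "PredictionWithUncertainty",
    "DeviationMaps",
    "fit_normative",
    "predict",
    "compute_z",
    "crossvalidated_z",
    "evaluate_model",
    "forward_model_slopes",
]

# log-hyperparameter bounds: (v_c, v_l, v_f, length-scale), then noise s2_n
_COV_BOUNDS = [(-10.0, 6.0), (-10.0, 6.0), (-10.0, 6.0), (np.log(0.05), np.log(50.0))]
_NOISE_BOUNDS = (-12.0, 4.0)
_JITTER_START = 1e-6
_JITTER_MAX = 1e-2


class PredictionWithUncertainty(NamedTuple):
    """GP predictions on the original data scale.

    ``var_total = var_function + noise_variance`` is the variance of a new
    observation and is the denominator of the normative Z-score.
    """

    mean: np.ndarray          # (n_query, V)
    var_function: np.ndarray  # (n_query, V) posterior variance of the mean
    var_total: np.ndarray     # (n_query, V)


@dataclass
class DeviationMaps:
    """Subjects x voxels normative Z-scores with per-subject provenance.

    ``provenance[i]`` is ``"cv"`` for healthy subjects scored out-of-fold and
    ``"transfer"`` for subjects scored by a model trained on all healthy
    subjects.
    """

    Z: np.ndarray
    provenance: np.ndarray
    cv_folds: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("deviation maps contain non-finite values")


def _sq_dists(XA: np.ndarray, XB: np.ndarray) -> np.ndarray:
    d = XA[:, None, :] - XB[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _kernel(XA: np.ndarray, XB: np.ndarray, log_theta: np.ndarray) -> np.ndarray:
    vc, vl, vf = np.exp(log_theta[:3])
    ell = np.exp(log_theta[3])
    K = vc + vl * (XA @ XB.T)
    K += vf * np.exp(-0.5 * _sq_dists(XA, XB) / ell**2)
    return K


def _kernel_diag(X: np.ndarray, log_theta: np.ndarray) -> np.ndarray:
    vc, vl, vf = np.exp(log_theta[:3])
    return vc + vl * np.einsum("ij,ij->i", X, X) + vf


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor, escalating jitter 1e-6..1e-2 of the max diagonal."""
    try:
        return linalg.cholesky(K, lower=True), 0.0
    except linalg.LinAlgError:
        pass
    scale = float(np.max(np.diag(K)))
    jitter = _JITTER_START
    while jitter <= _JITTER_MAX:
        try:
            L = linalg.cholesky(K + jitter * scale * np.eye(len(K)), lower=True)
            return L, jitter * scale
        except linalg.LinAlgError:
            jitter *= 10.0
    raise linalg.LinAlgError(
        "kernel matrix singular even after jitter up to "
        f"{_JITTER_MAX:g} * max diagonal"
    )


def _nlml_and_grad(log_params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative log marginal likelihood and gradient wrt log hyperparameters.

    ``log_params`` = (log v_c, log v_l, log v_f, log l, log s2_n).
    """
    n = len(y)
    cov, log_s2 = log_params[:4], log_params[4]
    D2 = _sq_dists(X, X)
    vc, vl, vf = np.exp(cov[:3])
    ell = np.exp(cov[3])
    E = np.exp(-0.5 * D2 / ell**2)
    K = vc + vl * (X @ X.T) + vf * E + np.exp(log_s2) * np.eye(n)

    L, _ = _chol_with_jitter(K)
    alpha = linalg.cho_solve((L, True), y)
    nlml = (np.sum(np.log(np.diag(L))) + 0.5 * y @ alpha
            + 0.5 * n * np.log(2.0 * np.pi))

    Kinv = linalg.cho_solve((L, True), np.eye(n))
    W = Kinv - np.outer(alpha, alpha)  # d(-lml)/dK = W/2
    grads = np.empty(5)
    grads[0] = 0.5 * vc * W.sum()
    grads[1] = 0.5 * vl * np.sum(W * (X @ X.T))
    grads[2] = 0.5 * vf * np.sum(W * E)
    grads[3] = 0.5 * vf * np.sum(W * E * (D2 / ell**2))
    grads[4] = 0.5 * np.exp(log_s2) * np.trace(W)
    return nlml, grads


def _optimize_voxel(X, y, rng, n_restarts: int) -> tuple[np.ndarray, float]:
    """Multi-restart L-BFGS over all 5 log hyperparameters for one voxel."""
    bounds = _COV_BOUNDS + [_NOISE_BOUNDS]
    best_params, best_val = None, np.inf
    inits = [np.array([np.log(0.1), np.log(0.5), np.log(0.5), 0.0, np.log(0.5)])]
    for _ in range(max(n_restarts - 1, 0)):
        inits.append(np.array([rng.uniform(lo / 2.0, hi / 2.0) for lo, hi in bounds]))
    for x0 in inits:
        res = optimize.minimize(
            _nlml_and_grad, x0, args=(X, y), jac=True, method="L-BFGS-B",
            bounds=bounds,
        )
        if res.fun < best_val:
            best_val, best_params = res.fun, res.x
    return best_params, best_val


class NormativeGPR(BaseEstimator):
    """Gaussian-process normative model, one GP per voxel.

    Parameters
    ----------
    hyperparams : {"tied", "per-voxel"}
        "tied" (default): covariance hyperparameters optimised on a random
        voxel subsample and median-pooled; per-voxel noise variance optimised
        exactly via the shared eigendecomposition.  "per-voxel": all five
        hyperparameters optimised independently per voxel (slow; intended for
        small problems).
    n_voxel_subsample : int
        Voxels used for the tied covariance optimisation.
    n_restarts : int
        Optimiser restarts per optimised voxel.
    random_state : int
        Seeds the subsample choice and restart initialisations.

    Attributes
    ----------
    cov_log_params_ : (4,) or (V, 4) log (v_c, v_l, v_f, length-scale)
    noise_variance_ : (V,) per-voxel s2_n on the standardized target scale
    noise_variance_raw_ : (V,) s2_n on the original target scale
    log_marginal_likelihood_ : (V,) per-voxel lml (standardized scale)
    x_mean_, x_std_, y_mean_, y_std_ : standardization statistics
    """

    def __init__(
        self,
        hyperparams: str = "tied",
        n_voxel_subsample: int = 15,
        n_restarts: int = 2,
        min_train: int = 20,
        random_state: int = 0,
    ):
        self.hyperparams = hyperparams
        self.n_voxel_subsample = n_voxel_subsample
        self.n_restarts = n_restarts
        self.min_train = min_train
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "NormativeGPR":
        """Fit per-voxel GPs.  X is (n, 2) raw (age, sex); Y is (n, V)."""
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, V = Y.shape
        if X.shape[0] != n:
            raise ValueError("X and Y disagree on the number of subjects")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("covariates and targets must be finite")
        if n < self.min_train:
            raise ValueError(
                f"need at least {self.min_train} training subjects, got {n}"
            )
        if self.hyperparams not in ("tied", "per-voxel"):
            raise ValueError("hyperparams must be 'tied' or 'per-voxel'")

        self.x_mean_ = X.mean(axis=0)
        x_std = X.std(axis=0)
        self.x_std_ = np.where(x_std > 0, x_std, 1.0)
        Xs = (X - self.x_mean_) / self.x_std_

        self.y_mean_ = Y.mean(axis=0)
        y_std = Y.std(axis=0)
        self.y_std_ = np.where(y_std > 0, y_std, 1.0)
        Ys = (Y - self.y_mean_) / self.y_std_

        rng = np.random.default_rng(self.random_state)
        if self.hyperparams == "per-voxel":
            self._fit_per_voxel(Xs, Ys, rng)
        else:
            self._fit_tied(Xs, Ys, rng)

        self.X_train_std_ = Xs
        self.n_voxels_ = V
        self.noise_variance_raw_ = self.noise_variance_ * self.y_std_**2
        return self

    def _fit_tied(self, Xs, Ys, rng) -> None:
        n, V = Ys.shape
        m = min(self.n_voxel_subsample, V)
        sub = rng.choice(V, size=m, replace=False)
        logs = np.empty((m, 4))
        for j, v in enumerate(sub):
            params, _ = _optimize_voxel(Xs, Ys[:, v], rng, self.n_restarts)
            logs[j] = params[:4]
        pooled = np.median(logs, axis=0)
        self.cov_log_params_ = pooled
        self.hyperparam_subsample_ = sub

        Ks = _kernel(Xs, Xs, pooled)
        # symmetric eigendecomposition of the shared signal kernel
        lam, Q = linalg.eigh(Ks)
        lam = np.clip(lam, 0.0, None)
        A = Q.T @ Ys                      # (n, V) rotated targets
        S = A**2

        # dense grid over log noise variance, then one parabolic refinement
        grid = np.linspace(*_NOISE_BOUNDS, 121)
        nll = np.empty((len(grid), V))
        for g, ls2 in enumerate(grid):
            denom = lam + np.exp(ls2)
            nll[g] = 0.5 * (np.log(denom).sum()
                            + (S / denom[:, None]).sum(axis=0)
                            + n * np.log(2.0 * np.pi))
        best = np.argmin(nll, axis=0)
        inner = np.clip(best, 1, len(grid) - 2)
        f0, f1, f2 = (nll[inner - 1, np.arange(V)], nll[inner, np.arange(V)],
                      nll[inner + 1, np.arange(V)])
        h = grid[1] - grid[0]
        denom_p = f0 - 2.0 * f1 + f2
        shift = np.where(denom_p > 0, 0.5 * h * (f0 - f2) / denom_p, 0.0)
        log_s2 = np.clip(grid[inner] + shift, *_NOISE_BOUNDS)
        # keep boundary optima at the boundary
        log_s2 = np.where(best == 0, grid[0], log_s2)
        log_s2 = np.where(best == len(grid) - 1, grid[-1], log_s2)

        s2 = np.exp(log_s2)
        denom = lam[:, None] + s2[None, :]
        self.noise_variance_ = s2
        self.log_marginal_likelihood_ = -0.5 * (
            np.log(denom).sum(axis=0) + (S / denom).sum(axis=0)
            + n * np.log(2.0 * np.pi)
        )
        self._lam, self._Q = lam, Q
        self._coef = Q @ (A / denom)      # (n, V): (K + s2 I)^-1 y per voxel

    def _fit_per_voxel(self, Xs, Ys, rng) -> None:
        n, V = Ys.shape
        cov = np.empty((V, 4))
        s2 = np.empty(V)
        lml = np.empty(V)
        for v in range(V):
            params, val = _optimize_voxel(Xs, Ys[:, v], rng, self.n_restarts)
            cov[v] = params[:4]
            s2[v] = np.exp(params[4])
            lml[v] = -val
        self.cov_log_params_ = cov
        self.noise_variance_ = s2
        self.log_marginal_likelihood_ = lml
        # per-voxel solves cached lazily in predict
        self._coef = None
        self._Ys = Ys

    # -- prediction -------------------------------------------------------

    def _check_support(self, Xq: np.ndarray) -> None:
        lo, hi = self._train_age_range_
        ages = Xq[:, 0]
        if ages.min() < lo or ages.max() > hi:
            warnings.warn(
                "query covariates outside the fitted age range "
                f"[{lo:.1f}, {hi:.1f}]; extrapolating",
                UserWarning, stacklevel=3,
            )

    @property
    def _train_age_range_(self) -> tuple[float, float]:
        ages = self.X_train_std_[:, 0] * self.x_std_[0] + self.x_mean_[0]
        return float(ages.min()), float(ages.max())

    def predict(self, X: np.ndarray, warn_extrapolation: bool = True
                ) -> PredictionWithUncertainty:
        """Posterior mean and variance at new covariates, de-standardized."""
        if not hasattr(self, "X_train_std_"):
            raise AttributeError("model is not fitted")
        Xq = np.atleast_2d(np.asarray(X, dtype=float))
        if warn_extrapolation:
            self._check_support(Xq)
        Xqs = (Xq - self.x_mean_) / self.x_std_

        if self.hyperparams == "tied":
            mean_s, var_f_s = self._predict_tied(Xqs)
        else:
            mean_s, var_f_s = self._predict_per_voxel(Xqs)

        var_f_s = np.clip(var_f_s, 0.0, None)
        mean = self.y_mean_ + self.y_std_ * mean_s
        var_f = var_f_s * self.y_std_**2
        var_total = var_f + self.noise_variance_raw_
        return PredictionWithUncertainty(mean, var_f, var_total)

    def _predict_tied(self, Xqs):
        theta = self.cov_log_params_
        Kstar = _kernel(Xqs, self.X_train_std_, theta)   # (q, n)
        mean = Kstar @ self._coef                        # (q, V)
        U = Kstar @ self._Q                              # (q, n)
        denom = self._lam[:, None] + self.noise_variance_[None, :]
        var_f = _kernel_diag(Xqs, theta)[:, None] - (U**2) @ (1.0 / denom)
        return mean, var_f

    def _predict_per_voxel(self, Xqs):
        Xs = self.X_train_std_
        n, V = self._Ys.shape
        q = len(Xqs)
        mean = np.empty((q, V))
        var_f = np.empty((q, V))
        for v in range(V):
            theta = self.cov_log_params_[v]
            K = _kernel(Xs, Xs, theta) + self.noise_variance_[v] * np.eye(n)
            L, _ = _chol_with_jitter(K)
            Kstar = _kernel(Xqs, Xs, theta)
            alpha = linalg.cho_solve((L, True), self._Ys[:, v])
            mean[:, v] = Kstar @ alpha
            Vmat = linalg.solve_triangular(L, Kstar.T, lower=True)
            var_f[:, v] = _kernel_diag(Xqs, theta) - np.einsum(
                "ij,ij->j", Vmat, Vmat
            )
        return mean, var_f


# -- module-level operations ---------------------------------------------


def fit_normative(
    Y_healthy: np.ndarray,
    X_healthy: np.ndarray,
    hyperparams: str = "tied",
    n_voxel_subsample: int = 15,
    n_restarts: int = 2,
    seed: int = 0,
) -> NormativeGPR:
    """Fit the normative model on healthy subjects (thin estimator wrapper)."""
    model = NormativeGPR(
        hyperparams=hyperparams,
        n_voxel_subsample=n_voxel_subsample,
        n_restarts=n_restarts,
        random_state=seed,
    )
    return model.fit(X_healthy, Y_healthy)


def predict(fit: NormativeGPR, X: np.ndarray) -> PredictionWithUncertainty:
    return fit.predict(X)


def compute_z(
    observed: np.ndarray,
    prediction: PredictionWithUncertainty,
    provenance: str = "transfer",
) -> DeviationMaps:
    """Normative Z = (y - yhat) / sqrt(var_total)."""
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    if observed.shape != prediction.mean.shape:
        raise ValueError(
            f"observed shape {observed.shape} != prediction shape "
            f"{prediction.mean.shape}"
        )
    if np.any(prediction.var_total <= 0):
        raise ValueError("var_total must be strictly positive for Z-scores")
    Z = (observed - prediction.mean) / np.sqrt(prediction.var_total)
    prov = np.full(len(Z), provenance, dtype=object)
    return DeviationMaps(Z=Z, provenance=prov)


def crossvalidated_z(
    Y_healthy: np.ndarray,
    X_healthy: np.ndarray,
    k: int = 10,
    stratify_sex: bool = True,
    seed: int = 0,
    return_predictions: bool = False,
    **fit_kwargs,
) -> DeviationMaps | tuple[DeviationMaps, PredictionWithUncertainty]:
    """Out-of-fold normative Z for every healthy subject under k-fold CV.

    Folds are a random partition (stratified by sex by default) with sizes
    within one of each other; the model is refit from scratch on each
    training split.
    """
    Y = np.asarray(Y_healthy, dtype=float)
    X = np.asarray(X_healthy, dtype=float)
    n = len(Y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of healthy subjects ({n})")

    sex = X[:, 1].astype(int)
    if stratify_sex and len(np.unique(sex)) > 1 and np.bincount(sex).min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, sex)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)

    Z = np.empty_like(Y)
    mean = np.empty_like(Y)
    var_f = np.empty_like(Y)
    var_t = np.empty_like(Y)
    folds = np.empty(n, dtype=int)
    for fold_id, (train, test) in enumerate(split_iter, start=1):
        model = fit_normative(Y[train], X[train], seed=seed, **fit_kwargs)
        pred = model.predict(X[test], warn_extrapolation=False)
        Z[test] = (Y[test] - pred.mean) / np.sqrt(pred.var_total)
        mean[test], var_f[test], var_t[test] = pred
        folds[test] = fold_id

    prov = np.full(n, "cv", dtype=object)
    maps = DeviationMaps(Z=Z, provenance=prov, cv_folds=folds)
    if return_predictions:
        return maps, PredictionWithUncertainty(mean, var_f, var_t)
    return maps


def evaluate_model(
    predicted: np.ndarray, observed: np.ndarray
) -> np.ndarray:
    """Per-voxel Pearson correlation between out-of-sample predictions and
    observations.  Zero-variance voxels yield NaN."""
    P = np.asarray(predicted, dtype=float)
    O = np.asarray(observed, dtype=float)
    if P.shape != O.shape:
        raise ValueError("predicted and observed shapes differ")
    Pc = P - P.mean(axis=0)
    Oc = O - O.mean(axis=0)
    denom = np.sqrt((Pc**2).sum(axis=0) * (Oc**2).sum(axis=0))
    zero_var = (np.ptp(P, axis=0) == 0) | (np.ptp(O, axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Pc * Oc).sum(axis=0) / denom
    r[zero_var | (denom == 0)] = np.nan
    return r


def correlation_display_masks(
    r: np.ndarray, p: np.ndarray | None = None,
    r_threshold: float = 0.4, one_minus_p_threshold: float = 0.095,
) -> dict[str, np.ndarray]:
    """Display masks for model-evaluation maps: |r| above threshold and,
    if p-values are supplied, 1-p above threshold."""
    masks = {"abs_r": np.abs(r) > r_threshold}
    if p is not None:
        masks["one_minus_p"] = (1.0 - p) > one_minus_p_threshold
    return masks


def forward_model_slopes(
    fit: NormativeGPR, age_range: tuple[float, float] = (20.0, 70.0)
) -> dict[str, np.ndarray]:
    """Linear approximation of the normative trajectory per sex.

    slope(sex) = (yhat(age_hi, sex) - yhat(age_lo, sex)) / (age_hi - age_lo)
    per voxel, plus the male - female slope difference map.
    """
    lo, hi = age_range
    queries = np.array([[lo, 0.0], [hi, 0.0], [lo, 1.0], [hi, 1.0]])
    pred = fit.predict(queries, warn_extrapolation=False)
    span = hi - lo
    female = (pred.mean[1] - pred.mean[0]) / span
    male = (pred.mean[3] - pred.mean[2]) / span
    return {
        "slope_female": female,
        "slope_male": male,
        "slope_difference": male - female,
    }


def tail_probability(z: float) -> float:
    """Upper-tail standard normal probability, 1 - Phi(z)."""
    return float(stats.norm.sf(z))
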