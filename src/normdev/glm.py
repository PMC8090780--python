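"""Voxel-wise general linear model on deviation maps with permutation FWER.

Group contrasts (e.g. HC - SZ) are tested per voxel by OLS t-statistics;
inference is by label permutation, with family-wise error control from the
permutation distribution of the voxel-wise maximum of the same signed
statistic (max-statistic correction).  With nuisance regressors present,
permutation follows the Freedman-Lane scheme: residuals from the reduced
(nuisance-only) model are permuted, the nuisance fit is added back, and the
full-model statistic is recomputed.

Contrasts are directional (one-sided); two-sided results are obtained by
reporting a contrast and its reverse as a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DesignSpec", "GLMFit", "GLMResult", "build_group_design",
           "fit_glm", "permutation_inference"]


@dataclass
class DesignSpec:
    """Design matrix, named contrast vectors and permutation settings."""

    design: np.ndarray
    contrasts: dict[str, np.ndarray]
    n_permutations: int = 10000
    seed: int = 0
    nuisance_columns: tuple[int, ...] = ()
    column_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        X = np.asarray(self.design, dtype=float)
        if X.ndim != 2:
            raise ValueError("design must be 2-D")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            names = self.column_names or tuple(
                f"col{j}" for j in range(X.shape[1])
            )
            raise ValueError(
                f"design is rank-deficient (rank {rank} < {X.shape[1]} "
                f"columns {names}); drop collinear columns"
            )
        for name, c in self.contrasts.items():
            if len(np.asarray(c)) != X.shape[1]:
                raise ValueError(
                    f"contrast {name!r} length != design columns"
                )
        object.__setattr__(self, "design", X)


def build_group_design(
    groups, levels=("HC", "BP", "SZ"), pairs=None
) -> DesignSpec:
    """Cell-means design (one indicator column per group) with all pairwise
    directional contrasts (both directions per pair)."""
    groups = np.asarray(groups)
    present = [g for g in levels if np.any(groups == g)]
    X = np.column_stack([(groups == g).astype(float) for g in present])
    idx = {g: j for j, g in enumerate(present)}
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(present)
                 for b in present[i + 1:]]
    contrasts = {}
    for a, b in pairs:
        c = np.zeros(len(present))
        c[idx[a]], c[idx[b]] = 1.0, -1.0
        contrasts[f"{a}-{b}"] = c
        contrasts[f"{b}-{a}"] = -c
    return DesignSpec(design=X, contrasts=contrasts,
                      column_names=tuple(present))


@dataclass
class GLMFit:
    beta: np.ndarray                  # (p, V)
    t: dict[str, np.ndarray]          # contrast -> (V,)
    sigma2: np.ndarray                # (V,) residual variance
    df: int
    zero_variance: np.ndarray         # (V,) bool flag


@dataclass
class GLMResult:
    t_observed: dict[str, np.ndarray]
    p_uncorrected: dict[str, np.ndarray]   # one-sided permutation p per voxel
    p_fwer: dict[str, np.ndarray]          # max-statistic corrected p
    group_mean_z: dict[str, np.ndarray]
    n_permutations: int
    zero_variance: np.ndarray


def _t_stats(Y, X, pinvX, XtXinv, contrasts, df):
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    scale = np.einsum("ij,ij->j", Y, Y) / len(Y) + np.finfo(float).tiny
    zero = sigma2 <= 1e-12 * scale
    t = {}
    for name, c in contrasts.items():
        se2 = sigma2 * float(c @ XtXinv @ c)
        with np.errstate(invalid="ignore", divide="ignore"):
            tv = (c @ beta) / np.sqrt(se2)
        tv[zero] = 0.0
        t[name] = tv
    return beta, t, sigma2, zero


def fit_glm(Z: np.ndarray, spec: DesignSpec) -> GLMFit:
    """Per-voxel OLS fit with t-statistics for each contrast.

    Zero-variance voxels (residual variance numerically zero) are flagged
    and their t set to 0.
    """
    Z = np.asarray(Z, dtype=float)
    X = spec.design
    n, p = X.shape
    if Z.shape[0] != n:
        raise ValueError("Z rows != design rows")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} subjects for {p} columns")
    df = n - p
    pinvX = np.linalg.pinv(X)
    XtXinv = np.linalg.inv(X.T @ X)
    beta, t, sigma2, zero = _t_stats(Z, X, pinvX, XtXinv, spec.contrasts, df)
    return GLMFit(beta=beta, t=t, sigma2=sigma2, df=df, zero_variance=zero)


def permutation_inference(Z: np.ndarray, spec: DesignSpec) -> GLMResult:
    """Label-permutation inference with max-statistic FWER correction.

    Per contrast c, the one-sided uncorrected p at voxel v is
    ``(1 + #{perm: t_perm,v >= t_obs,v}) / (n_perm + 1)`` and the corrected
    p uses the permutation distribution of ``max_v t_perm,v`` of the same
    signed statistic, so corrected >= uncorrected always holds and the
    smallest achievable p is 1/(n_perm + 1).  Deterministic given
    ``spec.seed``.
    """
    Z = np.asarray(Z, dtype=float)
    if spec.n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    X = spec.design
    n, p = X.shape
    df = n - p
    rng = np.random.default_rng(spec.seed)
    pinvX = np.linalg.pinv(X)
    XtXinv = np.linalg.inv(X.T @ X)

    _, t_obs, _, zero = _t_stats(Z, X, pinvX, XtXinv, spec.contrasts, df)

    if spec.nuisance_columns:
        nuis = list(spec.nuisance_columns)
        Xn = X[:, nuis]
        fit_n = Xn @ np.linalg.pinv(Xn) @ Z
        resid_n = Z - fit_n
    else:
        fit_n, resid_n = None, None

    exceed = {name: np.zeros(Z.shape[1]) for name in spec.contrasts}
    exceed_max = {name: np.zeros(Z.shape[1]) for name in spec.contrasts}
    for _ in range(spec.n_permutations):
        perm = rng.permutation(n)
        if resid_n is None:
            Yp = Z[perm]
        else:
            Yp = fit_n + resid_n[perm]   # Freedman-Lane
        _, t_perm, _, _ = _t_stats(Yp, X, pinvX, XtXinv, spec.contrasts, df)
        for name in spec.contrasts:
            tp = t_perm[name]
            exceed[name] += tp >= t_obs[name]
            exceed_max[name] += tp.max() >= t_obs[name]

    denom = spec.n_permutations + 1
    p_unc = {k: (1.0 + v) / denom for k, v in exceed.items()}
    p_fwer = {k: (1.0 + v) / denom for k, v in exceed_max.items()}

    group_mean_z = {}
    # cell-means columns (0/1 indicators) admit per-group mean maps
    names = spec.column_names or tuple(f"col{j}" for j in range(p))
    for j, name in enumerate(names):
        col = X[:, j]
        if set(np.unique(col)) <= {0.0, 1.0} and col.sum() > 0:
            group_mean_z[name] = Z[col == 1].mean(axis=0)

    return GLMResult(
        t_observed=t_obs, p_uncorrected=p_unc, p_fwer=p_fwer,
        group_mean_z=group_mean_z, n_permutations=spec.n_permutations,
        zero_variance=zero,
    )
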