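"""Extreme-deviation metrics on normative Z-maps.

A voxel is an extreme negative (positive) deviation when Z < -z (Z > +z) for
a per-tail threshold z, or when it survives a per-subject Benjamini-Hochberg
FDR step-up on two-sided normal p-values.  Per-subject summaries are the
percentage of in-mask voxels in each tail and an extreme-value summary (the
mean of the top 1% of |Z|), to which a Gumbel distribution can be fit across
subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "z_from_p",
    "p_from_z",
    "threshold_npm",
    "fdr_threshold_npm",
    "extreme_percentages",
    "evs_statistic",
    "extreme_score_table",
    "fit_extreme_value_distribution",
    "EVDFit",
]


def z_from_p(p: float) -> float:
    """Per-tail threshold: z such that P(Z > z) = p under the standard normal."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(stats.norm.isf(p))


def p_from_z(z: float) -> float:
    """Per-tail exceedance probability for threshold z."""
    return float(stats.norm.sf(z))


def threshold_npm(z_row: np.ndarray, z_thr: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a normative probability map into extreme tails.

    Strict inequalities: negative mask is Z < -z_thr, positive is Z > +z_thr.
    Works on a single map (V,) or a stack (n, V).
    """
    if z_thr <= 0:
        raise ValueError("z_thr must be positive")
    z = np.asarray(z_row, dtype=float)
    return z < -z_thr, z > z_thr


def fdr_threshold_npm(
    z_row: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg thresholding of a subject's map.

    Two-sided p = 2(1 - Phi(|Z|)) per voxel; the BH step-up runs within the
    subject's own in-mask voxels (each map is that subject's family);
    survivors are split by the sign of Z.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    z = np.asarray(z_row, dtype=float)
    single = z.ndim == 1
    z2 = np.atleast_2d(z)
    p = 2.0 * stats.norm.sf(np.abs(z2))
    p_adj = stats.false_discovery_control(p, axis=1, method="bh")
    survive = p_adj <= q
    neg = survive & (z2 < 0)
    pos = survive & (z2 > 0)
    if single:
        return neg[0], pos[0]
    return neg, pos


def extreme_percentages(
    negative_mask: np.ndarray, positive_mask: np.ndarray, n_mask_voxels: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage of in-mask voxels in each tail.

    ``n_mask_voxels`` defaults to the mask length of the inputs (i.e. the
    masks are assumed to span the whole brain mask).
    """
    neg = np.asarray(negative_mask, dtype=bool)
    pos = np.asarray(positive_mask, dtype=bool)
    V = neg.shape[-1] if n_mask_voxels is None else int(n_mask_voxels)
    if V <= 0:
        raise ValueError("mask voxel count must be positive")
    return (
        100.0 * neg.sum(axis=-1) / V,
        100.0 * pos.sum(axis=-1) / V,
    )


def evs_statistic(
    z_row: np.ndarray, top_fraction: float = 0.01, trim_upper: float = 0.0
) -> float | np.ndarray:
    """Extreme-value summary: mean of the top ``top_fraction`` of |Z|.

    ``ceil(top_fraction * V)`` voxels enter the mean.  ``trim_upper``
    optionally discards that fraction of the very largest values inside the
    selected set before averaging (alternative reading of a trimmed mean of
    the tail; default keeps all selected values).
    """
    z = np.asarray(z_row, dtype=float)
    V = z.shape[-1]
    if V < 100:
        raise ValueError(f"need at least 100 in-mask voxels, got {V}")
    k = math.ceil(top_fraction * V)
    top = np.sort(np.abs(z), axis=-1)[..., -k:]
    if trim_upper > 0:
        drop = int(math.floor(trim_upper * k))
        if drop:
            top = top[..., :-drop]
    return top.mean(axis=-1)


def extreme_score_table(
    Z: np.ndarray,
    subject_ids,
    thresholds=(1.96, 2.6, 3.1),
    fdr_q: float | None = 0.05,
    n_mask_voxels: int | None = None,
) -> pd.DataFrame:
    """Per-subject extreme scores, one row per subject x threshold spec."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    evs = evs_statistic(Z)
    frames = []
    for thr in thresholds:
        neg, pos = threshold_npm(Z, thr)
        pct_neg, pct_pos = extreme_percentages(neg, pos, n_mask_voxels)
        frames.append(pd.DataFrame({
            "subject_id": subject_ids,
            "threshold": f"|Z|>{thr:g}",
            "pct_negative": pct_neg,
            "pct_positive": pct_pos,
            "evs_stat": evs,
        }))
    if fdr_q is not None:
        neg, pos = fdr_threshold_npm(Z, fdr_q)
        pct_neg, pct_pos = extreme_percentages(neg, pos, n_mask_voxels)
        frames.append(pd.DataFrame({
            "subject_id": subject_ids,
            "threshold": f"FDR q={fdr_q:g}",
            "pct_negative": pct_neg,
            "pct_positive": pct_pos,
            "evs_stat": evs,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class EVDFit:
    """Maximum-likelihood Gumbel (or GEV) fit to per-subject extreme summaries."""

    family: str
    location: float
    scale: float
    shape: float | None
    log_likelihood: float
    qq_max_abs_deviation: float
    degenerate: bool = False


def fit_extreme_value_distribution(
    values: np.ndarray, family: str = "gumbel"
) -> EVDFit:
    """Fit an extreme value distribution to per-subject summaries by MLE.

    Gumbel is the default family (the limiting law for maxima of
    light-tailed variables); a generalized extreme value fit is available
    with ``family="gev"``.  Returns location/scale (and shape for GEV) with
    log-likelihood and the maximum absolute QQ deviation as diagnostics.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 10:
        raise ValueError("need a 1-D array of at least 10 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        return EVDFit(family=family, location=float(x[0]), scale=0.0,
                      shape=0.0 if family == "gev" else None,
                      log_likelihood=np.inf, qq_max_abs_deviation=0.0,
                      degenerate=True)

    if family == "gumbel":
        loc, scale = stats.gumbel_r.fit(x)
        dist = stats.gumbel_r(loc=loc, scale=scale)
        shape = None
    elif family == "gev":
        c, loc, scale = stats.genextreme.fit(x)
        dist = stats.genextreme(c, loc=loc, scale=scale)
        shape = float(c)
    else:
        raise ValueError("family must be 'gumbel' or 'gev'")

    loglik = float(dist.logpdf(x).sum())
    probs = (np.arange(1, len(x) + 1) - 0.5) / len(x)
    qq_dev = float(np.max(np.abs(np.sort(x) - dist.ppf(probs))))
    return EVDFit(family=family, location=float(loc), scale=float(scale),
                  shape=shape, log_likelihood=loglik,
                  qq_max_abs_deviation=qq_dev)
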