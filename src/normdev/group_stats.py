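"""Nonparametric group inference on extreme-deviation scores.

Pairwise Mann-Whitney U tests between diagnostic groups (exact enumeration
for very small samples, tie-corrected normal approximation otherwise) with
Bonferroni-Holm correction across the comparison family, correlations of the
scores with symptom/clinical covariates (pooled across patient groups and
within groups), and the prevalence ratio of group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney",
    "holm_adjust",
    "correlate_scores",
    "CorrelationResult",
    "prevalence_ratio",
    "group_comparisons",
    "symptom_correlations",
]


def mann_whitney(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of scores in group A vs group B.

    Uses the exact null distribution when min(n_A, n_B) <= 8 and there are
    no ties across the pooled sample; otherwise the normal approximation
    with tie correction and continuity correction.  Returns (U_A, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # identical constant in both groups: no evidence either way
        return float(len(a) * len(b) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class CorrelationResult:
    metric: str
    covariate: str
    scope: str
    r: float
    p: float
    n: int
    method: str


def correlate_scores(
    scores: np.ndarray,
    covariate: np.ndarray,
    metric: str = "score",
    covariate_name: str = "covariate",
    scope: str = "pooled",
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate per-subject extreme scores with a clinical covariate.

    Pairs with a missing covariate (e.g. PANSS for healthy controls) are
    dropped.  Zero-variance inputs yield NaN r and p.
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(covariate, dtype=float)
    keep = np.isfinite(s) & np.isfinite(c)
    s, c = s[keep], c[keep]
    if len(s) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(s) == 0 or np.ptp(c) == 0:
        return CorrelationResult(metric, covariate_name, scope,
                                 np.nan, np.nan, len(s), method)
    if method == "pearson":
        r, p = stats.pearsonr(s, c)
    elif method == "spearman":
        r, p = stats.spearmanr(s, c)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(metric, covariate_name, scope,
                             float(r), float(p), len(s), method)


def prevalence_ratio(mean_patient: float, mean_healthy: float) -> float:
    """Ratio of group means of extreme-negative percentages, to two decimals."""
    if mean_healthy <= 0:
        raise ValueError("healthy group mean must be positive")
    return round(float(mean_patient) / float(mean_healthy), 2)


def group_comparisons(
    score_table: pd.DataFrame,
    cohort: pd.DataFrame,
    metrics=("pct_negative", "pct_positive", "evs_stat"),
    pairs=(("HC", "SZ"), ("HC", "BP"), ("BP", "SZ")),
    holm_family: str = "per-metric",
) -> pd.DataFrame:
    """All pairwise group comparisons of the extreme scores.

    ``score_table`` is one threshold slice of
    :func:`normdev.metrics.extreme_score_table` merged against group labels
    by subject_id.  The Holm family is, by default, the set of group pairs
    within each metric (``holm_family="per-metric"``); ``"all"`` corrects
    across every row at once.
    """
    merged = score_table.merge(cohort[["subject_id", "group"]], on="subject_id")
    rows = []
    for metric in metrics:
        for ga, gb in pairs:
            a = merged.loc[merged["group"] == ga, metric].to_numpy()
            b = merged.loc[merged["group"] == gb, metric].to_numpy()
            U, p = mann_whitney(a, b)
            rows.append({
                "group_a": ga, "group_b": gb, "metric": metric,
                "U": U, "p_raw": p,
                "direction": "A>B" if np.mean(a) > np.mean(b) else "A<B",
                "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b)),
            })
    out = pd.DataFrame(rows)
    if holm_family == "per-metric":
        out["p_holm"] = np.nan
        for metric in metrics:
            sel = out["metric"] == metric
            out.loc[sel, "p_holm"] = holm_adjust(out.loc[sel, "p_raw"].to_numpy())
    elif holm_family == "all":
        out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    else:
        raise ValueError("holm_family must be 'per-metric' or 'all'")
    return out


def symptom_correlations(
    score_table: pd.DataFrame,
    cohort: pd.DataFrame,
    metrics=("pct_negative", "pct_positive"),
    covariates=("panss_total", "panss_positive", "panss_negative",
                "panss_global", "age_of_onset"),
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlations of extreme scores with clinical covariates.

    Computed pooled across the patient groups (BP and SZ; healthy controls
    have no symptom scores and drop out) and within each patient group.
    """
    merged = score_table.merge(
        cohort[["subject_id", "group", *covariates]], on="subject_id"
    )
    patients = merged[merged["group"].isin(["BP", "SZ"])]
    scopes = {"pooled BP&SZ": patients}
    for g in ("BP", "SZ"):
        scopes[g] = patients[patients["group"] == g]
    rows = []
    for scope_name, frame in scopes.items():
        if len(frame) < 3:
            continue
        for metric in metrics:
            for cov in covariates:
                if cov not in frame:
                    continue
                try:
                    res = correlate_scores(
                        frame[metric].to_numpy(), frame[cov].to_numpy(),
                        metric=metric, covariate_name=cov,
                        scope=scope_name, method=method,
                    )
                except ValueError:
                    continue
                rows.append(vars(res))
    return pd.DataFrame(rows)
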