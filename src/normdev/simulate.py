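"""Synthetic cohort and voxel-wise gray-matter data generator.

Emulates the statistical structure of smoothed voxel-based-morphometry (VBM)
gray-matter maps in a case-control psychosis cohort so that the whole
normative-modeling pipeline is testable without access to clinical MRI data:

* demographics and symptom scores (PANSS) for healthy controls (HC),
  bipolar-disorder (BP) and schizophrenia (SZ) groups, with realistic group
  means and sex ratios;
* a smooth mean gray-matter surface that declines with age at parcel-specific
  rates (steepest in designated "frontal" parcels) and carries a sex offset;
* spatially correlated Gaussian noise, produced by smoothing a white field to
  a configurable FWHM and rescaling so that every voxel's marginal standard
  deviation is exactly ``noise_sd`` (keeps Z-calibration analytic);
* a diffuse, group-shared gray-matter deficit in the vulnerable parcels of
  patient groups: the robust group-level case-control effect;
* idiosyncratic focal lesions in patients: per-subject Poisson counts of
  spherical, cosine-tapered negative blobs whose centers are biased toward
  vulnerable parcels but otherwise independent across subjects, so group maps
  show consistent loci while individual overlap stays sparse.

The generator's ground truth (parcel slopes, lesion fields, noise sd) is
returned alongside the data and is hidden from the analysis stages by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .voxel import VoxelSpace, ellipsoid_mask

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "generate_cohort",
    "generate_voxel_data",
]

GROUPS = ("HC", "BP", "SZ")

#: Reference age at which the mean surface equals ``baseline_gm``.
AGE_REF = 45.0

# Demographic / symptom presets: a 3T case-control psychosis sample with
# n = 400 HC / 116 BP / 94 SZ, group-specific age distributions, sex ratios
# and PANSS component means (positive, negative, general) with SZ > BP.
_AGE_MEAN = {"HC": 34.0, "BP": 31.0, "SZ": 28.0}
_AGE_SD = {"HC": 11.3, "BP": 10.8, "SZ": 9.2}
_MALE_FRAC = {"HC": 0.5025, "BP": 0.3534, "SZ": 0.5744}
_PANSS_MEAN = {  # (positive, negative, global/general)
    "BP": (9.3, 9.6, 25.5),
    "SZ": (13.4, 15.7, 30.6),
}
_PANSS_SD = {"BP": (3.2, 5.3, 5.3), "SZ": (4.3, 6.4, 7.6)}
_PANSS_FLOOR = (7, 7, 16)  # instrument minima per component
_ONSET_MEAN = {"BP": 27.0, "SZ": 23.0}


class ConfigurationError(ValueError):
    """Raised for invalid or non-finite generator configuration values."""


@dataclass
class GeneratorConfig:
    """All tunable knobs of the synthetic cohort.

    Defaults define the reference study conditions used throughout the test
    suite: a 20x24x20 grid with an ellipsoidal mask (~3,700 voxels), 8
    parcels with age slopes from -0.004 to -0.001 units/year, 8 mm-like
    smoothing (FWHM 2 voxels), noise sd 0.05, and lesion rates
    lambda_SZ = 4, lambda_BP = 1, lambda_HC = 0 with amplitudes calibrated
    so extreme-negative deviations (|Z| > 2.6 tail) are roughly four times
    more prevalent in SZ than in HC.
    """

    n_hc: int = 400
    n_bp: int = 116
    n_sz: int = 94
    dims: tuple[int, int, int] = (20, 24, 20)
    voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_parcels: int = 8
    n_frontal_parcels: int = 2
    baseline_gm: float = 0.5
    age_slope_range: tuple[float, float] = (-0.004, -0.001)
    age_range: tuple[float, float] = (20.0, 70.0)
    sex_offset: float = 0.02
    noise_sd: float = 0.05
    smoothing_fwhm_vox: float = 2.0
    lesion_rate: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "BP": 1.0, "SZ": 4.0}
    )
    lesion_amplitude: tuple[float, float] = (-0.24, -0.14)
    lesion_radius_vox: float = 3.0
    vulnerability_weight: float = 3.0
    # diffuse, group-shared gray-matter deficit in the vulnerable parcels
    # (volume units): the robust group-level effect, distinct from the
    # idiosyncratic focal lesions that drive individual extreme deviations
    group_deficit: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "BP": 0.006, "SZ": 0.022}
    )
    male_lesion_multiplier: float = 1.0
    panss_burden_slope: float = 0.25  # PANSS-total points per lesion
    panss_noise_scale: float = 1.0
    onset_burden_slope: float = 0.5  # years earlier onset per lesion
    seed: int = 0

    def validate(self) -> None:
        scalars = {
            "baseline_gm": self.baseline_gm,
            "sex_offset": self.sex_offset,
            "noise_sd": self.noise_sd,
            "smoothing_fwhm_vox": self.smoothing_fwhm_vox,
            "lesion_radius_vox": self.lesion_radius_vox,
            "vulnerability_weight": self.vulnerability_weight,
            "male_lesion_multiplier": self.male_lesion_multiplier,
            "panss_burden_slope": self.panss_burden_slope,
            "panss_noise_scale": self.panss_noise_scale,
            "onset_burden_slope": self.onset_burden_slope,
            **{f"lesion_rate[{g}]": r for g, r in self.lesion_rate.items()},
            **{f"group_deficit[{g}]": v for g, v in self.group_deficit.items()},
            **{f"age_slope_range[{i}]": s for i, s in enumerate(self.age_slope_range)},
            **{f"lesion_amplitude[{i}]": a for i, a in enumerate(self.lesion_amplitude)},
        }
        for name, value in scalars.items():
            if not math.isfinite(float(value)):
                raise ConfigurationError(f"{name} is not finite: {value!r}")
        for name, n in (("n_hc", self.n_hc), ("n_bp", self.n_bp), ("n_sz", self.n_sz)):
            if n < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {n}")
        if any(r < 0 for r in self.lesion_rate.values()):
            raise ConfigurationError("lesion rates must be non-negative")
        if self.lesion_radius_vox < 0:
            raise ConfigurationError("lesion_radius_vox must be non-negative")
        if self.noise_sd < 0 or self.smoothing_fwhm_vox < 0:
            raise ConfigurationError("noise_sd and smoothing_fwhm_vox must be >= 0")
        if self.n_parcels < 1 or self.n_frontal_parcels > self.n_parcels:
            raise ConfigurationError("need 1 <= n_frontal_parcels <= n_parcels")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        for key in ("dims", "voxel_size", "age_slope_range", "age_range",
                    "lesion_amplitude"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the per-subject covariate table.

    Returns a DataFrame with columns ``subject_id, age, sex, group,
    panss_positive, panss_negative, panss_global, panss_total, age_of_onset,
    lesion_burden_true``.  PANSS and onset fields are missing (NaN) for HC.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    counts = {"HC": config.n_hc, "BP": config.n_bp, "SZ": config.n_sz}

    rows: list[dict[str, Any]] = []
    lo, hi = config.age_range
    for group in GROUPS:
        n = counts[group]
        if n == 0:
            continue
        ages = _truncnorm(rng, _AGE_MEAN[group], _AGE_SD[group], lo, hi, n)
        sexes = (rng.random(n) < _MALE_FRAC[group]).astype(int)
        lam = config.lesion_rate.get(group, 0.0)
        rates = lam * np.where(sexes == 1, config.male_lesion_multiplier, 1.0)
        burdens = rng.poisson(rates)
        for age, sex, burden in zip(ages, sexes, burdens):
            row: dict[str, Any] = {
                "age": float(age),
                "sex": int(sex),
                "group": group,
                "lesion_burden_true": int(burden),
            }
            if group == "HC":
                row.update(
                    panss_positive=np.nan, panss_negative=np.nan,
                    panss_global=np.nan, panss_total=np.nan, age_of_onset=np.nan,
                )
            else:
                comps = []
                # split the total burden slope across components 30/40/30
                for mean_c, sd_c, floor_c, share in zip(
                    _PANSS_MEAN[group], _PANSS_SD[group], _PANSS_FLOOR,
                    (0.3, 0.4, 0.3),
                ):
                    beta_c = config.panss_burden_slope * share
                    val = (mean_c + beta_c * (burden - lam)
                           + rng.normal(0.0, sd_c * config.panss_noise_scale))
                    comps.append(max(int(round(val)), floor_c))
                onset = (_ONSET_MEAN[group]
                         - config.onset_burden_slope * (burden - lam)
                         + rng.normal(0.0, 5.0))
                onset = float(np.clip(onset, 12.0, age - 0.5))
                row.update(
                    panss_positive=comps[0], panss_negative=comps[1],
                    panss_global=comps[2], panss_total=sum(comps),
                    age_of_onset=onset,
                )
            rows.append(row)

    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "age", "sex", "group", "panss_positive",
                     "panss_negative", "panss_global", "panss_total",
                     "age_of_onset", "lesion_burden_true"]
        )
    cohort = pd.DataFrame(rows)
    cohort.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(len(cohort))])
    return cohort


def _parcel_labels(space: VoxelSpace, n_parcels: int) -> np.ndarray:
    """Partition in-mask voxels into contiguous slabs along the first axis.

    Parcel 0 sits at the lowest x coordinates (the designated "frontal" end).
    """
    x = space.coords[:, 0].astype(float)
    qs = np.quantile(x, np.linspace(0, 1, n_parcels + 1)[1:-1])
    return np.searchsorted(qs, x, side="right").astype(int)


def _smoothing_kernels(sigma: float, n_axes: int = 3):
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    return [k] * n_axes


def _smooth_and_rescale(white: np.ndarray, sigma: float, noise_sd: float) -> np.ndarray:
    """Smooth white noise (zero-padded boundary) and rescale so every voxel's
    marginal sd is exactly ``noise_sd``.

    The per-voxel variance of the linear filter is computed analytically from
    the squared separable kernel, so the rescaling contract is exact, not
    empirical.
    """
    if sigma <= 0 or noise_sd == 0:
        return white * noise_sd
    kernels = _smoothing_kernels(sigma)
    out = white
    var = np.ones(white.shape[-3:])
    for axis, k in enumerate(kernels):
        out = ndimage.correlate1d(out, k, axis=out.ndim - 3 + axis, mode="constant")
        var = ndimage.correlate1d(var, k ** 2, axis=axis, mode="constant")
    return out / np.sqrt(var) * noise_sd


def _lesion_field(
    coords: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Sum of cosine-tapered spherical blobs over the in-mask voxels."""
    contrib = np.zeros(len(coords))
    for center, amp in zip(centers, amplitudes):
        d = np.linalg.norm(coords - center, axis=1)
        inside = d <= radius
        contrib[inside] += amp * 0.5 * (1.0 + np.cos(np.pi * d[inside] / radius))
    return contrib


def generate_voxel_data(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> tuple[VoxelSpace, np.ndarray, dict[str, Any]]:
    """Generate the (subjects x voxels) gray-matter matrix and ground truth.

    Per subject ``i`` and voxel ``v``::

        y_iv = baseline + slope[parcel(v)] * (age_i - 45)
               + sex_offset(v) * sex_i + lesion_i(v) + eps_iv

    with ``eps`` a smoothed Gaussian field rescaled to ``noise_sd`` per voxel.
    Lesion counts are taken from ``cohort.lesion_burden_true``; centers are
    drawn with probability proportional to the vulnerability map.

    Returns ``(space, Y, truth)`` where ``truth`` records parcel labels,
    per-parcel slopes, the sex-offset map, per-voxel noise sd, and per-subject
    lesion geometry (centers, amplitudes, the additive lesion field, and the
    count of voxels any lesion touches).
    """
    config.validate()
    if len(cohort) == 0:
        raise ValueError("cohort is empty; nothing to simulate")
    required = {"age", "sex", "group", "lesion_burden_true"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")

    rng = np.random.default_rng([int(config.seed), 1])
    mask = ellipsoid_mask(config.dims)
    space = VoxelSpace(tuple(config.dims), tuple(config.voxel_size), mask)
    V = space.n_voxels
    coords = space.coords.astype(float)

    parcels = _parcel_labels(space, config.n_parcels)
    slope_steep, slope_shallow = config.age_slope_range
    slopes = np.linspace(slope_steep, slope_shallow, config.n_parcels)
    frontal = np.arange(config.n_frontal_parcels)
    voxel_slope = slopes[parcels]

    sex_offset_map = np.where(np.isin(parcels, frontal), config.sex_offset, 0.0)
    vuln = np.where(np.isin(parcels, frontal), config.vulnerability_weight, 1.0)
    vuln_p = vuln / vuln.sum()

    ages = cohort["age"].to_numpy(float)
    sexes = cohort["sex"].to_numpy(int)
    burdens = cohort["lesion_burden_true"].to_numpy(int)
    n = len(cohort)

    deficit = np.array([config.group_deficit.get(g, 0.0)
                        for g in cohort["group"]])
    vuln_indicator = np.isin(parcels, frontal).astype(float)
    mean_surface = (
        config.baseline_gm
        + np.outer(ages - AGE_REF, voxel_slope)
        + np.outer(sexes, sex_offset_map)
        - np.outer(deficit, vuln_indicator)
    )

    sigma = config.smoothing_fwhm_vox / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    white = rng.standard_normal((n, *config.dims))
    noise = _smooth_and_rescale(white, sigma, config.noise_sd)[:, mask]

    lesion_field = np.zeros((n, V), dtype=np.float32)
    lesion_records: list[dict[str, Any]] = []
    amp_lo, amp_hi = sorted(config.lesion_amplitude)
    for i in range(n):
        k = int(burdens[i])
        if k == 0:
            lesion_records.append({"centers": np.empty((0, 3)), "amplitudes": np.empty(0)})
            continue
        centers = coords[rng.choice(V, size=k, p=vuln_p)]
        amplitudes = rng.uniform(amp_lo, amp_hi, size=k)
        lesion_field[i] = _lesion_field(
            coords, centers, amplitudes, config.lesion_radius_vox
        )
        lesion_records.append({"centers": centers, "amplitudes": amplitudes})

    Y = mean_surface + noise + lesion_field

    truth = {
        "parcel_labels": parcels,
        "parcel_slopes": slopes,
        "frontal_parcels": frontal,
        "voxel_slope": voxel_slope,
        "sex_offset_map": sex_offset_map,
        "vulnerability_map": vuln_p,
        "group_deficit": dict(config.group_deficit),
        "noise_sd": np.full(V, config.noise_sd),
        "baseline_gm": config.baseline_gm,
        "age_ref": AGE_REF,
        "mean_surface": mean_surface,
        "lesion_field": lesion_field,
        "lesions": lesion_records,
        "lesion_voxel_counts": (lesion_field != 0).sum(axis=1),
    }
    return space, Y, truth
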