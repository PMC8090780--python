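"""Voxel-wise overlap of extreme deviations across individuals.

The overlap map of a group is, per voxel, the proportion of the group's
subjects whose thresholded deviation map is extreme there.  Peak value and
location summarise how spatially consistent the individual deviations are;
sex stratification splits each group's map by sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .voxel import VoxelSpace

__all__ = ["OverlapMap", "overlap_map", "stratified_overlap", "peak_table"]


@dataclass
class OverlapMap:
    """Per-voxel overlap proportions for one group (and optionally stratum)."""

    group: str
    proportion: np.ndarray        # (V,) in [0, 1]
    n_subjects: int
    peak_value: float             # percent
    peak_voxel: tuple[int, int, int] | None
    peak_voxels: list[tuple[int, int, int]]  # all tied peaks
    tail: str = "negative"
    threshold: str = ""
    stratum: str | None = None


def _single_overlap(masks: np.ndarray, group: str, space: VoxelSpace | None,
                    tail: str, threshold: str, stratum: str | None) -> OverlapMap:
    n = masks.shape[0]
    prop = masks.mean(axis=0)
    peak = float(prop.max())
    tied = np.flatnonzero(prop == peak)
    if space is not None:
        coords = [tuple(int(c) for c in xyz) for xyz in space.coords_of(tied)]
    else:
        coords = [(int(j), -1, -1) for j in tied]
    return OverlapMap(
        group=group, proportion=prop, n_subjects=n,
        peak_value=100.0 * peak,
        peak_voxel=coords[0] if coords else None,  # ties: lowest flat index
        peak_voxels=coords, tail=tail, threshold=threshold, stratum=stratum,
    )


def overlap_map(
    masks: np.ndarray,
    groups,
    space: VoxelSpace | None = None,
    tail: str = "negative",
    threshold: str = "",
) -> dict[str, OverlapMap]:
    """Overlap maps per group from per-subject extreme-voxel masks.

    ``masks`` is (n_subjects, V) boolean; ``groups`` the per-subject labels.
    Raises for an empty mask stack; a group absent from ``groups`` simply
    does not appear in the result.
    """
    masks = np.asarray(masks, dtype=bool)
    groups = np.asarray(groups)
    if masks.ndim != 2 or masks.shape[0] == 0:
        raise ValueError("masks must be a non-empty (subjects, voxels) array")
    if len(groups) != masks.shape[0]:
        raise ValueError("group labels do not match the mask stack")
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        out[str(g)] = _single_overlap(
            masks[sel], str(g), space, tail, threshold, None
        )
    return out


def stratified_overlap(
    masks: np.ndarray,
    groups,
    strata,
    space: VoxelSpace | None = None,
    tail: str = "negative",
    threshold: str = "",
) -> dict[str, dict[str, OverlapMap]]:
    """Overlap maps per group x stratum (e.g. sex).

    Empty strata within a group are skipped with a warning.  Returns
    ``{group: {stratum: OverlapMap}}``.
    """
    masks = np.asarray(masks, dtype=bool)
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    if len(strata) != masks.shape[0]:
        raise ValueError("stratum labels do not match the mask stack")
    levels = pd.unique(strata)
    out: dict[str, dict[str, OverlapMap]] = {}
    for g in pd.unique(groups):
        out[str(g)] = {}
        for s in levels:
            sel = (groups == g) & (strata == s)
            if not sel.any():
                warnings.warn(
                    f"stratum {s!r} empty within group {g!r}; skipped",
                    UserWarning, stacklevel=2,
                )
                continue
            out[str(g)][str(s)] = _single_overlap(
                masks[sel], str(g), space, tail, threshold, str(s)
            )
    return out


def peak_table(maps) -> pd.DataFrame:
    """Flatten overlap maps into a peak summary table."""
    rows = []
    def _collect(m: OverlapMap):
        rows.append({
            "group": m.group, "stratum": m.stratum, "tail": m.tail,
            "threshold": m.threshold, "n_subjects": m.n_subjects,
            "peak_pct": m.peak_value,
            "peak_x": m.peak_voxel[0] if m.peak_voxel else None,
            "peak_y": m.peak_voxel[1] if m.peak_voxel else None,
            "peak_z": m.peak_voxel[2] if m.peak_voxel else None,
            "n_tied_peaks": len(m.peak_voxels),
        })
    for value in maps.values():
        if isinstance(value, dict):
            for sub in value.values():
                _collect(sub)
        else:
            _collect(value)
    return pd.DataFrame(rows)
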