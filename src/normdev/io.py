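"""File I/O: cohort tables (TSV), NIfTI volumes, masks, JSON manifests.

Conventions: 0-based voxel coordinates everywhere, identity affine for
synthetic data, masks strictly boolean, in-mask values lossless at the dtype
written (float64 by default).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .voxel import VoxelSpace

__all__ = [
    "read_cohort", "write_cohort",
    "write_mask", "read_mask",
    "write_stack", "read_stack",
    "write_map", "read_map",
    "sha256_of", "write_manifest", "read_manifest",
]

_NA = "NA"


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False, na_rep=_NA)
    return path


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA])


def _affine(space: VoxelSpace) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = space.voxel_size
    return aff


def write_mask(space: VoxelSpace, path) -> Path:
    img = nib.Nifti1Image(space.mask.astype(np.uint8), _affine(space))
    nib.save(img, str(path))
    return Path(path)


def read_mask(path, voxel_size=None) -> VoxelSpace:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.isin(np.unique(data), [0, 1]).all():
        raise ValueError("mask volume must be strictly binary")
    vs = voxel_size or tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelSpace(tuple(data.shape), tuple(vs), data.astype(bool))


def _check_geometry(img, space: VoxelSpace) -> None:
    if tuple(img.shape[:3]) != tuple(space.dims):
        raise ValueError(
            f"volume dims {img.shape[:3]} do not match mask dims {space.dims}"
        )
    if not np.allclose(img.affine, _affine(space), atol=1e-4):
        raise ValueError("volume affine does not match the mask affine")


def write_stack(values: np.ndarray, space: VoxelSpace, path,
                dtype=np.float64) -> Path:
    """Write an (n_subjects, V) matrix as a 4D NIfTI (x, y, z, subject)."""
    values = np.atleast_2d(np.asarray(values))
    vol = np.zeros((*space.dims, values.shape[0]), dtype=dtype)
    vol[space.mask, :] = values.T
    nib.save(nib.Nifti1Image(vol, _affine(space)), str(path))
    return Path(path)


def read_stack(path, space: VoxelSpace) -> np.ndarray:
    img = nib.load(str(path))
    _check_geometry(img, space)
    vol = np.asarray(img.dataobj)
    if vol.ndim == 3:
        vol = vol[..., None]
    return vol[space.mask, :].T


def write_map(values: np.ndarray, space: VoxelSpace, path,
              dtype=np.float64) -> Path:
    """Write a length-V vector as a 3D NIfTI volume."""
    nib.save(
        nib.Nifti1Image(space.to_grid(np.asarray(values, dtype=dtype)),
                        _affine(space)),
        str(path),
    )
    return Path(path)


def read_map(path, space: VoxelSpace) -> np.ndarray:
    img = nib.load(str(path))
    _check_geometry(img, space)
    return np.asarray(img.dataobj)[space.mask]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
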