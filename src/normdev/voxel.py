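"""Voxel grid geometry: 3D mask and the mask <-> flat-column bijection.

All subject-level data matrices in this package are (n_subjects, n_voxels)
arrays whose columns enumerate the in-mask voxels of a :class:`VoxelSpace`
in C (row-major) order.  Voxel coordinates in tables and reports are
0-based grid indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VoxelSpace:
    """Grid geometry plus binary brain mask.

    Parameters
    ----------
    dims : tuple of int
        Grid shape (nx, ny, nz).
    voxel_size : tuple of float
        Voxel edge length in mm per axis.
    mask : ndarray of bool, shape ``dims``
        Brain mask; ``True`` voxels carry data columns.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.dims):
            raise ValueError(f"mask shape {mask.shape} != dims {self.dims}")
        if not mask.any():
            raise ValueError("mask contains no voxels")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (= data column count)."""
        return int(self.mask.sum())

    @property
    def flat_index(self) -> np.ndarray:
        """Flat grid indices (C order) of the in-mask voxels, ascending.

        Column ``j`` of a data matrix lives at grid position
        ``np.unravel_index(flat_index[j], dims)``.
        """
        return np.flatnonzero(self.mask.ravel(order="C"))

    @property
    def coords(self) -> np.ndarray:
        """(V, 3) 0-based grid coordinates of the in-mask voxels."""
        return np.argwhere(self.mask)

    def coords_of(self, columns: np.ndarray) -> np.ndarray:
        """Grid coordinates of the given data columns."""
        cols = np.atleast_1d(np.asarray(columns, dtype=int))
        idx = np.array(np.unravel_index(self.flat_index[cols], self.dims)).T
        return idx

    def to_grid(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-V vector back onto the 3D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} values, got {values.shape[-1]}"
            )
        out = np.full(self.dims, fill, dtype=values.dtype)
        out[self.mask] = values
        return out

    def from_grid(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask values of a 3D (or 4D, last-axes grid) volume."""
        volume = np.asarray(volume)
        if volume.shape[-3:] != tuple(self.dims):
            raise ValueError(
                f"volume grid shape {volume.shape[-3:]} != dims {self.dims}"
            )
        return volume[..., self.mask]


def ellipsoid_mask(dims: tuple[int, int, int], margin: float = 1.0) -> np.ndarray:
    """Axis-aligned ellipsoidal mask inscribed in the grid.

    Semi-axes are ``dims/2 - margin``; mimics a brain mask sitting inside
    the bounding box with a rim of background voxels.
    """
    dims = tuple(int(d) for d in dims)
    centers = [(d - 1) / 2.0 for d in dims]
    semi = [max(d / 2.0 - margin, 0.5) for d in dims]
    grids = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centers, semi))
    return r2 <= 1.0
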