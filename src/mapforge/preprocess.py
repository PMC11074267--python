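"""Density-map standardization: resampling to a uniform voxel grid and
percentile normalization of density values into [0, 1].

Raw deposited maps come with heterogeneous voxel sizes and density scales;
both steps here remove that cross-map variation so downstream voxel
classifiers see comparable inputs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .gridio import DensityGrid


class DegenerateMapError(ValueError):
    """The map has no strictly positive density values to normalize by."""


def resample(grid: DensityGrid, target_voxel: float = 1.0,
             order: int = 1) -> DensityGrid:
    """Resample a grid to a uniform voxel size via trilinear interpolation.

    The output covers the full bounding box of the input (``ceil(extent /
    target_voxel)`` voxels per axis); sample points beyond the input
    support take the value 0. The origin is unchanged. ``order=0`` selects
    nearest-neighbor interpolation, appropriate for integer label masks.

    Parameters
    ----------
    grid : DensityGrid
        Input volume.
    target_voxel : float
        Output voxel edge length in Angstrom (default 1.0).
    order : int
        Spline order for ``scipy.ndimage.map_coordinates``: 1 = trilinear
        (default), 0 = nearest neighbor.
    """
    if target_voxel <= 0:
        raise ValueError(f"target voxel size must be positive, got {target_voxel}")
    vx, vy, vz = grid.voxel_size
    nz, ny, nx = grid.data.shape
    out_shape = (
        max(1, math.ceil(nz * vz / target_voxel)),
        max(1, math.ceil(ny * vy / target_voxel)),
        max(1, math.ceil(nx * vx / target_voxel)),
    )
    if out_shape == grid.data.shape and grid.voxel_size == (target_voxel,) * 3:
        data = grid.data.copy()
    else:
        # output sample m along an axis sits at input index m * target / voxel
        scale = (target_voxel / vz, target_voxel / vy, target_voxel / vx)
        coords = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(out_shape, scale)),
            indexing="ij",
        )
        data = ndimage.map_coordinates(
            np.asarray(grid.data, dtype=np.float64),
            coords, order=order, mode="constant", cval=0.0,
        )
        if order == 0:
            data = data.astype(grid.data.dtype)
    return DensityGrid(
        data=data,
        voxel_size=(target_voxel,) * 3,
        origin=grid.origin,
        mode=grid.mode,
        labels=list(grid.labels),
    )


def normalize(grid: DensityGrid, percentile: float = 95.0) -> DensityGrid:
    """Scale densities by the given percentile of positive values, then clip.

    The divisor is the ``percentile``-th percentile (linear interpolation
    between order statistics) of the *strictly positive* values only; after
    division every value is clipped into [0, 1], so negative densities map
    to 0 and outliers above the divisor map to 1.

    Raises
    ------
    DegenerateMapError
        If the map contains no strictly positive value.
    """
    data = np.asarray(grid.data, dtype=np.float64)
    positives = data[data > 0]
    if positives.size == 0:
        raise DegenerateMapError("map has no positive density values")
    p = float(np.percentile(positives, percentile))
    out = np.clip(data / p, 0.0, 1.0)
    return DensityGrid(
        data=out,
        voxel_size=grid.voxel_size,
        origin=grid.origin,
        mode=2,
        labels=list(grid.labels),
    )
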