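"""Longitudinal averaging along the local bundle direction, plus an optional
isotropic Gaussian pre-filter.

Filament signal is coherent along the bundle axis while the noise is not, so
replacing each voxel with the mean of trilinear samples taken up and down the
local axis direction (default +/-15 slices) raises the signal-to-noise ratio
roughly with the square root of the window length without blurring across
filaments.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .axis_detection import AxisField, axis_at
from .exceptions import ValidationError
from .volume_io import DensityVolume

__all__ = ["longitudinal_average", "gaussian_filter"]


def longitudinal_average(
    vol: DensityVolume, field: AxisField, half_window: int = 15
) -> DensityVolume:
    """Average each voxel with samples along the local axis direction.

    ``out(p) = mean_k vol(p + k * v(p_y))`` for ``k = -half_window ...
    +half_window``, where ``v`` is the interpolated axis direction at the
    voxel's y and sampling is trilinear.  Samples falling outside the volume
    are dropped from the mean, which keeps the estimator unbiased at the
    borders.
    """
    if half_window < 0:
        raise ValidationError(f"half_window must be >= 0, got {half_window}")
    if half_window == 0:
        return DensityVolume(vol.data.copy(), vol.voxel_size_nm, vol.origin_nm)

    nx, ny, nz = vol.shape
    data = vol.data.astype(np.float64, copy=False)
    dirs = axis_at(field, np.arange(ny, dtype=float))  # (ny, 3)

    X = np.arange(nx, dtype=np.float64)[:, None, None]
    Y = np.arange(ny, dtype=np.float64)[None, :, None]
    Z = np.arange(nz, dtype=np.float64)[None, None, :]
    vx = dirs[:, 0][None, :, None]
    vy = dirs[:, 1][None, :, None]
    vz = dirs[:, 2][None, :, None]

    acc = np.zeros((nx, ny, nz), dtype=np.float64)
    cnt = np.zeros((nx, ny, nz), dtype=np.float64)
    for k in range(-half_window, half_window + 1):
        cx = np.broadcast_to(X + k * vx, (nx, ny, nz))
        cy = np.broadcast_to(Y + k * vy, (nx, ny, nz))
        cz = np.broadcast_to(Z + k * vz, (nx, ny, nz))
        valid = (
            (cx >= 0) & (cx <= nx - 1)
            & (cy >= 0) & (cy <= ny - 1)
            & (cz >= 0) & (cz <= nz - 1)
        )
        sampled = ndimage.map_coordinates(
            data, [cx, cy, cz], order=1, mode="nearest"
        )
        acc += np.where(valid, sampled, 0.0)
        cnt += valid
    out = acc / np.maximum(cnt, 1.0)
    return DensityVolume(out, vol.voxel_size_nm, vol.origin_nm)


def gaussian_filter(vol: DensityVolume, sigma: float) -> DensityVolume:
    """Isotropic Gaussian smoothing, truncated at 4 sigma; ``sigma=0`` is identity."""
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return DensityVolume(vol.data.copy(), vol.voxel_size_nm, vol.origin_nm)
    out = ndimage.gaussian_filter(vol.data.astype(np.float64, copy=False), sigma, truncate=4.0)
    return DensityVolume(out, vol.voxel_size_nm, vol.origin_nm)
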