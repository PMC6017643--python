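"""Bundle-axis estimation from 2D cross-correlation of cross-sections.

The bundle is roughly parallel to +y, so pairs of thickness-averaged X-Z
sections a fixed number of slices apart are cross-correlated; the sub-pixel
peak shift between them gives the local in-plane drift of the bundle, and
``normalize(dx, step, dz)`` the local direction vector.  A series of such
vectors sampled along y forms the :class:`AxisField`, interpolated by
:func:`axis_at`.

This is a fast alternative to 3D template matching: no rotational search is
needed because only the collective drift of the (rigid) hexagonal pattern is
estimated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import DegenerateInputError, ValidationError
from .volume_io import DensityVolume

__all__ = ["AxisField", "extract_section", "correlation_shift", "estimate_axis", "axis_at"]

log = logging.getLogger(__name__)


@dataclass
class AxisField:
    """Local bundle directions sampled along y.

    ``y_centers`` strictly increasing; ``directions`` unit 3-vectors with
    positive y component.
    """

    y_centers: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.y_centers = np.asarray(self.y_centers, dtype=float).reshape(-1)
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if len(self.y_centers) != len(self.directions) or len(self.y_centers) == 0:
            raise ValidationError("AxisField needs matching, non-empty samples")
        if not np.all(np.diff(self.y_centers) > 0):
            raise ValidationError("AxisField y_centers must be strictly increasing")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("AxisField directions must be unit-norm")
        if np.any(self.directions[:, 1] <= 0):
            raise ValidationError("AxisField directions must have positive y component")

    def __len__(self) -> int:
        return len(self.y_centers)

    @classmethod
    def constant(cls, direction=(0.0, 1.0, 0.0)) -> "AxisField":
        """A single-sample field, i.e. one global direction everywhere."""
        d = np.asarray(direction, dtype=float)
        return cls(y_centers=np.array([0.0]), directions=(d / np.linalg.norm(d))[None, :])


def extract_section(vol: DensityVolume, y: int, thickness: int) -> np.ndarray:
    """Mean of the X-Z planes over the slab ``[y, y + thickness)``."""
    if thickness < 1:
        raise ValidationError(f"thickness must be >= 1, got {thickness}")
    ny = vol.shape[1]
    if y < 0 or y + thickness > ny:
        raise ValidationError(
            f"slab [{y}, {y + thickness}) outside volume of length {ny} along y"
        )
    return vol.data[:, y : y + thickness, :].mean(axis=1, dtype=np.float64)


def correlation_shift(img_a: np.ndarray, img_b: np.ndarray) -> tuple[float, float]:
    """Sub-pixel shift (dx, dz) of ``img_b`` relative to ``img_a``.

    Computed as the peak of the zero-padded (linear) cross-correlation of the
    mean-subtracted images, refined by a 2D quadratic fit to the 3x3
    neighbourhood of the integer peak.  For ``img_b`` equal to ``img_a``
    translated by ``(tx, tz)`` the result is ``(tx, tz)``; adding a constant
    to either image does not change it.
    """
    a = np.asarray(img_a, dtype=np.float64)
    b = np.asarray(img_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValidationError(f"images must be 2D and same shape, got {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    if not (a.any() and b.any()):
        raise DegenerateInputError(
            "constant cross-section: correlation peak undefined up to offset"
        )
    # c[k] = sum_j b[j] * a[j - (k - (n-1))]; peak index k => shift k - (n-1)
    c = signal.fftconvolve(b, a[::-1, ::-1], mode="full")
    k = np.unravel_index(int(np.argmax(c)), c.shape)
    shift = np.array([k[0] - (a.shape[0] - 1), k[1] - (a.shape[1] - 1)], dtype=float)
    off = _quadratic_subpixel(c, k)
    return float(shift[0] + off[0]), float(shift[1] + off[1])


def _quadratic_subpixel(c: np.ndarray, k: tuple[int, int]) -> np.ndarray:
    """Stationary point of a 2D quadratic fit to the 3x3 patch around ``k``.

    Falls back to (0, 0) at the array border or when the fit has no interior
    maximum; the offset is clipped to one pixel.
    """
    i, j = k
    if not (0 < i < c.shape[0] - 1 and 0 < j < c.shape[1] - 1):
        return np.zeros(2)
    patch = c[i - 1 : i + 2, j - 1 : j + 2]
    u, w = np.meshgrid([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], indexing="ij")
    X = np.column_stack(
        [np.ones(9), u.ravel(), w.ravel(), (u**2).ravel(), (u * w).ravel(), (w**2).ravel()]
    )
    p, *_ = np.linalg.lstsq(X, patch.ravel(), rcond=None)
    hess = np.array([[2 * p[3], p[4]], [p[4], 2 * p[5]]])
    # require a negative-definite Hessian (a genuine peak)
    if hess[0, 0] >= 0 or np.linalg.det(hess) <= 0:
        return np.zeros(2)
    off = np.linalg.solve(hess, -np.array([p[1], p[2]]))
    return np.clip(off, -1.0, 1.0)


def estimate_axis(
    vol: DensityVolume,
    step: int = 55,
    thickness: int = 30,
    max_shift: float | None = None,
) -> AxisField:
    """Estimate the axis field from section pairs ``step`` slices apart.

    Sections are extracted at ``y = 0, step, 2*step, ...`` while they fit in
    the volume; each consecutive pair yields ``direction =
    normalize(dx, step, dz)`` assigned to the midpoint between the section
    centers.  Shifts beyond ``max_shift`` (default ``step * tan(30 deg)``,
    since bundles are roughly parallel to y) or degenerate correlations are
    dropped with a warning; an empty result is an error.
    """
    ny = vol.shape[1]
    if ny < step + thickness:
        raise ValidationError(
            f"volume length {ny} along y is shorter than step + thickness = {step + thickness}"
        )
    if max_shift is None:
        max_shift = step * math.tan(math.radians(30.0))

    starts = list(range(0, ny - thickness + 1, step))
    sections = [extract_section(vol, y, thickness) for y in starts]

    ys, dirs = [], []
    for idx in range(len(starts) - 1):
        try:
            dx, dz = correlation_shift(sections[idx], sections[idx + 1])
        except DegenerateInputError:
            log.warning("degenerate correlation for section pair at y=%d; sample omitted",
                        starts[idx])
            continue
        if math.hypot(dx, dz) > max_shift:
            log.warning("shift (%.2f, %.2f) at y=%d exceeds cap %.2f; sample omitted",
                        dx, dz, starts[idx], max_shift)
            continue
        d = np.array([dx, float(step), dz])
        dirs.append(d / np.linalg.norm(d))
        ys.append(starts[idx] + step / 2.0 + (thickness - 1) / 2.0)
    if not dirs:
        raise ValidationError("axis estimation failed: every section pair was degenerate")
    return AxisField(y_centers=np.asarray(ys), directions=np.asarray(dirs))


def axis_at(field: AxisField, y) -> np.ndarray:
    """Direction at (scalar or array) ``y``: piecewise-linear interpolation of
    the sampled directions, renormalized; constant beyond the first/last sample."""
    y = np.asarray(y, dtype=float)
    comps = [np.interp(y, field.y_centers, field.directions[:, c]) for c in range(3)]
    d = np.stack(comps, axis=-1)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    return d / norm
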