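"""Local quadratic polynomial kernel regression denoising.

At every voxel ``p`` a full 3-variable quadratic

    f(x, y, z) = a11 x^2 + a12 xy + a13 xz + a22 y^2 + a23 yz + a33 z^2
                 + b1 x + b2 y + b3 z + c

is fitted to the map by weighted least squares, the weight being an
anisotropic Gaussian ``W(x) = exp(-1/2 x H^-1 x^T)``.  The denoised value at
``p`` is ``f(p) = c`` (coordinates centered at ``p``).

``W`` is the convolution of two Gaussians and therefore Gaussian itself, with
covariance ``H = H_S + H_R``: a *shape kernel* S elongated along the filament
direction (sigma_long) with the filament thickness across it (sigma_thick),
and a *resolution kernel* R approximating the central peak of the
missing-wedge point-spread function — isotropic in XY (sigma_r) and twice as
wide along Z.

Because the weighted design matrix depends only on W, the fit collapses to a
linear "equivalent kernel" per direction; :func:`denoise` applies it as a
filter bank while :func:`local_fit` keeps the direct per-voxel solve (the two
agree exactly wherever the full support fits inside the volume).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .axis_detection import AxisField, axis_at
from .exceptions import RankDeficiencyError, ValidationError
from .volume_io import DensityVolume

__all__ = ["QuadraticPoly", "WeightKernel", "build_weight_kernel", "local_fit", "denoise"]

log = logging.getLogger(__name__)

_W_THRESHOLD = math.exp(-4.5)  # weights below exp(-9/2) * max are treated as zero


@dataclass
class QuadraticPoly:
    """Coefficients of the local quadratic: ``f(x) = x A x^T + b . x + c``.

    ``A`` is symmetric with off-diagonals ``a_ij / 2`` so that, e.g., the xy
    term of ``x A x^T`` is exactly ``a12 xy``; ten independent coefficients.
    """

    A: np.ndarray
    b: np.ndarray
    c: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(3, 3)
        self.b = np.asarray(self.b, dtype=float).reshape(3)
        if not np.allclose(self.A, self.A.T):
            raise ValidationError("A must be symmetric")
        self.c = float(self.c)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.einsum("ni,ij,nj->n", pts, self.A, pts) + pts @ self.b + self.c


@dataclass
class WeightKernel:
    """Gaussian weight W with covariance H = H_S + H_R and 3-sigma support."""

    H_S: np.ndarray
    H_R: np.ndarray
    H: np.ndarray
    support_radius_voxels: np.ndarray

    def __post_init__(self) -> None:
        for name in ("H_S", "H_R", "H"):
            M = np.asarray(getattr(self, name), dtype=float).reshape(3, 3)
            setattr(self, name, M)
            if not np.allclose(M, M.T):
                raise ValidationError(f"{name} must be symmetric")
            try:
                np.linalg.cholesky(M)
            except np.linalg.LinAlgError as exc:
                raise ValidationError(f"{name} must be positive definite") from exc
        if not np.allclose(self.H, self.H_S + self.H_R):
            raise ValidationError("H must equal H_S + H_R")
        self.support_radius_voxels = np.asarray(self.support_radius_voxels, float).reshape(3)

    def weights(self, offsets: np.ndarray) -> np.ndarray:
        """W at the given (n, 3) offsets, with the sub-threshold cut applied."""
        Hinv = np.linalg.inv(self.H)
        w = np.exp(-0.5 * np.einsum("ni,ij,nj->n", offsets, Hinv, offsets))
        w[w < _W_THRESHOLD] = 0.0
        return w


def build_weight_kernel(
    filament_dir, sigma_long: float, sigma_thick: float, sigma_r: float
) -> WeightKernel:
    """Construct W from the shape and resolution Gaussians.

    ``H_S`` has variance ``sigma_long^2`` along ``filament_dir`` and
    ``sigma_thick^2`` across it; ``H_R = diag(sigma_r^2, sigma_r^2,
    (2 sigma_r)^2)`` in the volume frame (Z doubled by the missing wedge).
    """
    d = np.asarray(filament_dir, dtype=float).reshape(3)
    if abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValidationError(f"filament_dir must be unit-norm, |d| = {np.linalg.norm(d):.6f}")
    if min(sigma_long, sigma_thick, sigma_r) <= 0:
        raise ValidationError("all sigmas must be > 0")
    # isotropic across the filament => no need for an explicit rotation matrix
    H_S = sigma_thick**2 * np.eye(3) + (sigma_long**2 - sigma_thick**2) * np.outer(d, d)
    H_R = np.diag([sigma_r**2, sigma_r**2, (2.0 * sigma_r) ** 2])
    H = H_S + H_R
    return WeightKernel(
        H_S=H_S, H_R=H_R, H=H, support_radius_voxels=3.0 * np.sqrt(np.diag(H))
    )


_MONOMIAL_DOC = "monomial order: x^2, xy, xz, y^2, yz, z^2, x, y, z, 1"


def _design(offsets: np.ndarray) -> np.ndarray:
    x, y, z = offsets[:, 0], offsets[:, 1], offsets[:, 2]
    return np.column_stack(
        [x * x, x * y, x * z, y * y, y * z, z * z, x, y, z, np.ones_like(x)]
    )


def _support_offsets(kernel: WeightKernel) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets in the truncated support box and their weights."""
    b = np.ceil(kernel.support_radius_voxels).astype(int)
    gx, gy, gz = (np.arange(-bb, bb + 1) for bb in b)
    O = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3).astype(float)
    w = kernel.weights(O)
    keep = w > 0
    return O[keep], w[keep]


def local_fit(
    vol: DensityVolume, p, kernel: WeightKernel
) -> tuple[QuadraticPoly, float]:
    """Direct weighted least-squares fit of the quadratic at voxel ``p``.

    Coordinates are centered at ``p``; the summation runs over the voxels of
    the truncated support that fall inside the volume.  Returns the
    coefficients and the denoised value ``f(p) = c``.
    """
    p = np.asarray(p, dtype=int).reshape(3)
    nx, ny, nz = vol.shape
    if not (0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz):
        raise ValidationError(f"point {tuple(p)} outside volume {vol.shape}")
    O, w = _support_offsets(kernel)
    q = O.astype(int) + p
    inside = (
        (q[:, 0] >= 0) & (q[:, 0] < nx)
        & (q[:, 1] >= 0) & (q[:, 1] < ny)
        & (q[:, 2] >= 0) & (q[:, 2] < nz)
    )
    O, w, q = O[inside], w[inside], q[inside]
    if len(O) < 10:
        raise RankDeficiencyError(
            f"only {len(O)} support voxels at {tuple(p)}: need >= 10 for a quadratic fit"
        )
    X = _design(O)
    phi = vol.data[q[:, 0], q[:, 1], q[:, 2]].astype(np.float64)
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], phi * sw, rcond=None)
    if rank < 10:
        raise RankDeficiencyError(f"rank-deficient weighted design (rank {rank}) at {tuple(p)}")
    a11, a12, a13, a22, a23, a33, b1, b2, b3, c = beta
    A = np.array(
        [[a11, a12 / 2, a13 / 2], [a12 / 2, a22, a23 / 2], [a13 / 2, a23 / 2, a33]]
    )
    return QuadraticPoly(A=A, b=np.array([b1, b2, b3]), c=float(c)), float(c)


def _equivalent_kernel(kernel: WeightKernel) -> np.ndarray:
    """The linear filter whose application equals the WLS fit value.

    value(p) = e_c^T (X^T W X)^-1 X^T W phi  =>  a fixed stencil over the
    support box (dense box; zero taps where W was cut).
    """
    b = np.ceil(kernel.support_radius_voxels).astype(int)
    O, w = _support_offsets(kernel)
    X = _design(O)
    XtW = X.T * w
    coef = np.linalg.solve(XtW @ X, XtW)  # (10, n_support)
    taps = coef[9]  # row selecting the constant term
    box = np.zeros(tuple(2 * b + 1))
    idx = (O + b).astype(int)
    box[idx[:, 0], idx[:, 1], idx[:, 2]] = taps
    return box


def denoise(
    vol: DensityVolume,
    field: AxisField,
    sigma_long: float = 8.0,
    sigma_thick: float = 2.0,
    sigma_r: float = 1.0,
) -> DensityVolume:
    """Denoise the whole volume by local quadratic kernel regression.

    The filament direction of the shape kernel is taken from the axis field
    at each voxel's y.  Voxels whose full support box does not fit inside the
    volume are copied from the input (their count is logged); the weighted
    design matrix is constant per direction, so each distinct direction's fit
    is applied as a single linear filter.
    """
    nx, ny, nz = vol.shape
    data = vol.data.astype(np.float64, copy=False)
    out = data.copy()
    dirs = axis_at(field, np.arange(ny, dtype=float))

    kernels: dict[tuple, np.ndarray] = {}
    copied = 0
    for y in range(ny):
        key = tuple(np.round(dirs[y], 9))
        if key not in kernels:
            wk = build_weight_kernel(dirs[y] / np.linalg.norm(dirs[y]),
                                     sigma_long, sigma_thick, sigma_r)
            kernels[key] = _equivalent_kernel(wk)
        eq = kernels[key]
        bx, by, bz = (s // 2 for s in eq.shape)
        if y < by or y >= ny - by or nx <= 2 * bx or nz <= 2 * bz:
            copied += nx * nz
            continue
        slab = data[:, y - by : y + by + 1, :]
        plane = signal.correlate(slab, eq, mode="valid", method="auto")[:, 0, :]
        out[bx : nx - bx, y, bz : nz - bz] = plane
        copied += nx * nz - plane.size
    if copied:
        log.info("denoise: %d border voxels copied from the input", copied)
    return DensityVolume(out, vol.voxel_size_nm, vol.origin_nm)
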