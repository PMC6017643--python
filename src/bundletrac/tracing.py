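"""Seed-based filament tracing by one-peak / seven-peak Gaussian matched filtering.

Each filament is traced from a single seed point by repeatedly placing the
next marker on a downstream cross-sectional slab.  The placement score is the
inner product of a zero-mean, unit-norm kernel — either a single 2D Gaussian
or seven Gaussians in a hexagon (one central peak plus the six nearest
neighbours of the bundle's packing) — with the slab patch at a candidate
position.  The seven-peak kernel exploits the local neighbourhood: even when
an individual filament's density is noisy or distorted, its six neighbours
pin the placement down.

At every step four downstream distances (default 10, 25, 45, 70 voxels) are
tried; the hexagon spacing and orientation are re-optimized within the
physical packing range (default 11-15 voxels) at each placement, and the
candidate with the best normalized score wins, ties going to the shortest
step.  The in-plane search radius grows linearly with step distance, which
enforces the gradual-direction-change premise of the bundle.

Implementation note: because the kernel is sampled on integer offsets and the
slab patch bilinearly, the score at a continuous position equals the bilinear
interpolation of the integer-lag cross-correlation map of slab and kernel.
Scores for the whole kernel bank are therefore computed once per slab with
batched FFTs on a half-voxel grid and shared by all filaments; a quadratic
sub-voxel refinement on the winning kernel's direct scores follows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

from .axis_detection import AxisField, axis_at
from .exceptions import ValidationError
from .volume_io import BundleModel, DensityVolume, FilamentTrace

__all__ = [
    "KernelSpec",
    "TraceParams",
    "SeedSet",
    "render_kernel",
    "score_placement",
    "optimize_placement",
    "next_marker",
    "trace_bundle",
    "seeds_from_model",
    "read_seeds",
    "write_seeds",
]

log = logging.getLogger(__name__)

_TIE_TOL = 1e-9  # relative score tolerance under which placements count as tied


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """One- or seven-peak 2D Gaussian tracing kernel.

    ``spacing_voxels`` (center-to-vertex distance) and ``theta_rad`` (hexagon
    orientation, in [0, pi/3) by 6-fold symmetry) only apply to 7 peaks.
    """

    n_peaks: int
    sigma_voxels: float
    spacing_voxels: float | None = None
    theta_rad: float | None = None

    def __post_init__(self) -> None:
        if self.n_peaks not in (1, 7):
            raise ValidationError(f"n_peaks must be 1 or 7, got {self.n_peaks}")
        if self.sigma_voxels <= 0:
            raise ValidationError(f"sigma_voxels must be > 0, got {self.sigma_voxels}")
        if self.n_peaks == 7:
            if self.spacing_voxels is None or self.spacing_voxels <= 0:
                raise ValidationError("7-peak kernel needs positive spacing_voxels")
            th = self.theta_rad or 0.0
            if not (0.0 <= th < math.pi / 3 + 1e-12):
                raise ValidationError(f"theta_rad must be in [0, pi/3), got {th}")

    @property
    def min_support(self) -> float:
        s = self.spacing_voxels if self.n_peaks == 7 else 0.0
        return (s or 0.0) + 3.0 * self.sigma_voxels


@dataclass(frozen=True)
class TraceParams:
    """Tunable tracing parameters (defaults are the method's standard settings)."""

    step_candidates: tuple[int, ...] = (10, 25, 45, 70)
    spacing_range: tuple[float, float] = (11.0, 15.0)
    spacing_step: float = 0.5
    theta_step_rad: float = math.pi / 36
    search_radius_voxels: float = 3.0  # max in-plane displacement per 10 voxels advanced
    max_displacement_voxels: float | None = None  # cap; default = search_radius_voxels
    section_thickness: int = 30
    sigma_voxels: float = 2.5

    def __post_init__(self) -> None:
        steps = tuple(int(s) for s in self.step_candidates)
        if not steps or any(s <= 0 for s in steps) or any(np.diff(steps) <= 0):
            raise ValidationError("step_candidates must be positive and strictly increasing")
        lo, hi = self.spacing_range
        if lo > hi or lo <= 0:
            raise ValidationError(f"invalid spacing_range {self.spacing_range}")
        if self.search_radius_voxels <= 0:
            raise ValidationError("search_radius_voxels must be > 0")
        if self.section_thickness < 1 or self.sigma_voxels <= 0:
            raise ValidationError("section_thickness >= 1 and sigma_voxels > 0 required")

    def spacings(self) -> np.ndarray:
        lo, hi = self.spacing_range
        n = int(round((hi - lo) / self.spacing_step))
        return lo + self.spacing_step * np.arange(n + 1)

    def thetas(self) -> np.ndarray:
        n = int(math.ceil(math.pi / 3 / self.theta_step_rad))
        return self.theta_step_rad * np.arange(n)

    @property
    def displacement_cap(self) -> float:
        """Hard per-step in-plane displacement cap.

        The axis-field prediction already compensates collective direction
        change, so the residual displacement of one filament per step does
        not grow with the step distance.  An uncapped linearly growing disc
        would let the search reach a neighbouring filament's score basin,
        which out-scores an edge filament's own position under the
        seven-peak kernel and drags rim filaments toward the bundle
        interior.  Defaults to ``search_radius_voxels``.
        """
        if self.max_displacement_voxels is not None:
            return self.max_displacement_voxels
        return self.search_radius_voxels

    def support_radius(self, n_peaks: int) -> int:
        s = self.spacing_range[1] if n_peaks == 7 else 0.0
        return int(math.ceil(s + 3.0 * self.sigma_voxels))


@dataclass
class SeedSet:
    """One in-plane (x, z) seed per filament on a starting slab at ``y0``."""

    points: np.ndarray
    y0: int
    slab_thickness: int = 30
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.y0 = int(self.y0)
        if self.slab_thickness < 1:
            raise ValidationError("slab_thickness must be >= 1")
        if self.ids is None:
            self.ids = [f"f{i:03d}" for i in range(len(self.points))]
        if len(self.ids) != len(self.points):
            raise ValidationError("ids and points length mismatch")

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# kernels and scores
# ---------------------------------------------------------------------------


def _peak_centers(spec: KernelSpec) -> np.ndarray:
    if spec.n_peaks == 1:
        return np.zeros((1, 2))
    th = spec.theta_rad or 0.0
    ang = th + np.arange(6) * (math.pi / 3)
    ring = spec.spacing_voxels * np.column_stack([np.cos(ang), np.sin(ang)])
    return np.vstack([[0.0, 0.0], ring])


def render_kernel(spec: KernelSpec, support_radius: int) -> np.ndarray:
    """Rasterize the kernel on ``[-R, R]^2``: unit-amplitude Gaussians at the
    peak centers, summed, then mean-subtracted and scaled to unit norm.

    The zero mean makes placement scores invariant to constant density
    offsets; the unit norm makes scores commensurable across kernels and
    across slabs at different step distances.
    """
    R = int(support_radius)
    if R < spec.min_support:
        raise ValidationError(
            f"support_radius {R} insufficient: kernel needs >= {spec.min_support:.1f}"
        )
    g = np.arange(-R, R + 1, dtype=float)
    X, Z = np.meshgrid(g, g, indexing="ij")
    k = np.zeros_like(X)
    for cx, cz in _peak_centers(spec):
        k += np.exp(-((X - cx) ** 2 + (Z - cz) ** 2) / (2.0 * spec.sigma_voxels**2))
    k -= k.mean()
    return k / np.linalg.norm(k)


_KERNEL_CACHE: dict[tuple, np.ndarray] = {}


def _kernel(spec: KernelSpec, R: int) -> np.ndarray:
    key = (spec.n_peaks, spec.sigma_voxels, spec.spacing_voxels, spec.theta_rad, R)
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = render_kernel(spec, R)
    return _KERNEL_CACHE[key]


def score_placement(
    section: np.ndarray,
    center: tuple[float, float],
    spec: KernelSpec,
    support_radius: int | None = None,
) -> float:
    """Matched-filter score of the kernel at a continuous in-plane position.

    Inner product of the rendered kernel with the section patch sampled
    bilinearly at ``center`` plus integer offsets.  The patch must lie fully
    inside the section.
    """
    section = np.asarray(section, dtype=np.float64)
    R = int(support_radius) if support_radius is not None else int(math.ceil(spec.min_support))
    cx, cz = float(center[0]), float(center[1])
    if cx - R < 0 or cz - R < 0 or cx + R > section.shape[0] - 1 or cz + R > section.shape[1] - 1:
        raise ValidationError(
            f"kernel support (radius {R}) around ({cx:.2f}, {cz:.2f}) exceeds "
            f"section of shape {section.shape}"
        )
    k = _kernel(spec, R)
    g = np.arange(-R, R + 1, dtype=float)
    coords = np.meshgrid(cx + g, cz + g, indexing="ij")
    patch = ndimage.map_coordinates(section, coords, order=1)
    return float(np.tensordot(k, patch, axes=2))


class _KernelBank:
    """All kernels scanned during local optimization, in tie-break order
    (spacing ascending, then theta ascending), with cached FFTs."""

    def __init__(self, params: TraceParams, n_peaks: int):
        self.R = params.support_radius(n_peaks)
        if n_peaks == 7:
            self.specs = [
                KernelSpec(7, params.sigma_voxels, float(s), float(t))
                for s in params.spacings()
                for t in params.thetas()
            ]
        else:
            self.specs = [KernelSpec(1, params.sigma_voxels)]
        self.kernels = np.stack([_kernel(s, self.R) for s in self.specs])
        self._fft_cache: dict[tuple, tuple] = {}

    def correlate(self, section: np.ndarray) -> np.ndarray:
        """Integer-lag valid-mode correlation maps, shape (n_kernels, m_x, m_z)
        where map ``[k, c - R]`` is the score of kernel k centered at integer c."""
        nx, nz = section.shape
        R = self.R
        if nx < 2 * R + 1 or nz < 2 * R + 1:
            raise ValidationError(
                f"section {section.shape} smaller than kernel support {2 * R + 1}"
            )
        shape_key = (nx, nz)
        if shape_key not in self._fft_cache:
            fsh = (sp_fft.next_fast_len(nx + 2 * R), sp_fft.next_fast_len(nz + 2 * R))
            flipped = self.kernels[:, ::-1, ::-1]
            self._fft_cache[shape_key] = (fsh, sp_fft.rfft2(flipped, s=fsh))
        fsh, kf = self._fft_cache[shape_key]
        sf = sp_fft.rfft2(section, s=fsh)
        conv = sp_fft.irfft2(sf[None, :, :] * kf, s=fsh)
        return conv[:, 2 * R : nx, 2 * R : nz]


def _upsample_half(c: np.ndarray) -> np.ndarray:
    """Exact bilinear values of a 2D map on the half-integer grid."""
    m, k = c.shape
    up = np.empty((2 * m - 1, 2 * k - 1), dtype=c.dtype)
    up[0::2, 0::2] = c
    up[1::2, 0::2] = 0.5 * (c[:-1, :] + c[1:, :])
    up[0::2, 1::2] = 0.5 * (c[:, :-1] + c[:, 1:])
    up[1::2, 1::2] = 0.25 * (c[:-1, :-1] + c[1:, :-1] + c[:-1, 1:] + c[1:, 1:])
    return up


def _score_maps(section: np.ndarray, bank: _KernelBank) -> tuple[np.ndarray, np.ndarray]:
    """Per-position best score and best-kernel index on the half-voxel grid.

    Kernels are scanned in (spacing, theta) order with strictly-greater
    updates, so ties keep the smallest spacing, then the smallest theta.
    """
    maps = bank.correlate(np.asarray(section, dtype=np.float64))
    best = _upsample_half(maps[0])
    arg = np.zeros(best.shape, dtype=np.uint16)
    for k in range(1, maps.shape[0]):
        up = _upsample_half(maps[k])
        mask = up > best
        best[mask] = up[mask]
        arg[mask] = k
    return best, arg


def _select(
    maps: tuple[np.ndarray, np.ndarray],
    bank: _KernelBank,
    init: tuple[float, float],
    radius: float,
) -> tuple[np.ndarray, int, float] | None:
    """Best half-grid placement within ``radius`` of ``init``.

    Ties (relative score within 1e-9) break to the smallest displacement from
    ``init``; remaining ties to row-major scan order.  Returns
    (position, kernel index, score) or None when no grid point is in range.
    """
    best, arg = maps
    R = bank.R
    ix, iz = float(init[0]), float(init[1])
    # half-grid index i corresponds to coordinate R + i/2
    i_lo = max(0, math.ceil(2 * (ix - radius - R)))
    i_hi = min(best.shape[0] - 1, math.floor(2 * (ix + radius - R)))
    j_lo = max(0, math.ceil(2 * (iz - radius - R)))
    j_hi = min(best.shape[1] - 1, math.floor(2 * (iz + radius - R)))
    if i_hi < i_lo or j_hi < j_lo:
        return None
    ii = np.arange(i_lo, i_hi + 1)
    jj = np.arange(j_lo, j_hi + 1)
    xs = R + ii / 2.0
    zs = R + jj / 2.0
    d2 = (xs[:, None] - ix) ** 2 + (zs[None, :] - iz) ** 2
    in_disc = d2 <= radius**2 + 1e-12
    if not in_disc.any():
        return None
    sub = best[i_lo : i_hi + 1, j_lo : j_hi + 1]
    scores = np.where(in_disc, sub, -np.inf)
    smax = scores.max()
    tol = _TIE_TOL * max(1.0, abs(smax))
    tied = scores >= smax - tol
    d2_tied = np.where(tied, d2, np.inf)
    flat = int(np.argmin(d2_tied))  # row-major argmin = deterministic scan order
    pi, pj = np.unravel_index(flat, d2_tied.shape)
    pos = np.array([xs[pi], zs[pj]])
    k_idx = int(arg[i_lo + pi, j_lo + pj])
    return pos, k_idx, float(scores[pi, pj])


def _refine(
    section: np.ndarray,
    pos: np.ndarray,
    spec: KernelSpec,
    R: int,
) -> tuple[np.ndarray, float]:
    """Sub-voxel refinement: 2D quadratic fit of the winning kernel's direct
    scores on a 3x3 stencil of *unit* spacing around the selected point.

    Unit spacing keeps every stencil point at the same fractional position,
    so the (slight, position-dependent) attenuation of bilinear patch
    sampling cancels out of the fit instead of biasing the peak estimate.
    """
    pos0 = np.asarray(pos, dtype=float)
    score0 = score_placement(section, tuple(pos0), spec, R)
    try:
        vals = np.array(
            [
                [score_placement(section, (pos0[0] + a, pos0[1] + b), spec, R)
                 for b in (-1, 0, 1)]
                for a in (-1, 0, 1)
            ]
        )
    except ValidationError:
        return pos0, score0
    u, w = np.meshgrid([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], indexing="ij")
    X = np.column_stack(
        [np.ones(9), u.ravel(), w.ravel(), (u**2).ravel(), (u * w).ravel(), (w**2).ravel()]
    )
    p, *_ = np.linalg.lstsq(X, vals.ravel(), rcond=None)
    hess = np.array([[2 * p[3], p[4]], [p[4], 2 * p[5]]])
    if hess[0, 0] >= 0 or np.linalg.det(hess) <= 0:
        return pos0, score0
    off = np.clip(np.linalg.solve(hess, -np.array([p[1], p[2]])), -1.0, 1.0)
    cand = pos0 + off
    try:
        return cand, score_placement(section, tuple(cand), spec, R)
    except ValidationError:
        return pos0, score0


_BANK_CACHE: dict[tuple, _KernelBank] = {}


def _bank(params: TraceParams, n_peaks: int) -> _KernelBank:
    key = (params, n_peaks)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = _KernelBank(params, n_peaks)
    return _BANK_CACHE[key]


def optimize_placement(
    section: np.ndarray,
    init: tuple[float, float],
    params: TraceParams,
    n_peaks: int,
    search_radius: float | None = None,
) -> tuple[np.ndarray, KernelSpec, float]:
    """Locally optimal kernel placement near ``init`` on one section.

    Grid search over position (half-voxel lattice within a disc of
    ``search_radius`` around ``init``) and, for seven peaks, over hexagon
    spacing and orientation; followed by quadratic sub-voxel refinement of
    the winning kernel's score surface.  Ties break to the smallest
    displacement from ``init``, then smallest spacing, then smallest theta.
    """
    bank = _bank(params, n_peaks)
    maps = _score_maps(section, bank)
    r = params.search_radius_voxels if search_radius is None else float(search_radius)
    sel = _select(maps, bank, init, r)
    if sel is None:
        raise ValidationError(
            f"no admissible placement within {r} voxels of {tuple(init)}: search disc "
            "lies outside the region where the kernel support fits the section"
        )
    pos, k_idx, _ = sel
    spec = bank.specs[k_idx]
    pos, score = _refine(np.asarray(section, dtype=np.float64), pos, spec, bank.R)
    return pos, spec, score


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------


class _Tracer:
    """Shared per-volume state: y-cumulative sums for O(1) slab means and
    cached half-grid score maps per slab, reused across filaments."""

    def __init__(self, vol: DensityVolume, field: AxisField, params: TraceParams, n_peaks: int):
        self.vol = vol
        self.field = field
        self.params = params
        self.n_peaks = n_peaks
        self.bank = _bank(params, n_peaks)
        data = vol.data.astype(np.float64, copy=False)
        self._cs = np.concatenate(
            [np.zeros((data.shape[0], 1, data.shape[2])), np.cumsum(data, axis=1)], axis=1
        )
        self._maps: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._sections: dict[tuple[int, int], np.ndarray] = {}

    def section(self, w0: int, t: int) -> np.ndarray:
        key = (w0, t)
        if key not in self._sections:
            self._sections[key] = (self._cs[:, w0 + t, :] - self._cs[:, w0, :]) / t
        return self._sections[key]

    def maps(self, w0: int, t: int) -> tuple[np.ndarray, np.ndarray]:
        key = (w0, t)
        if key not in self._maps:
            self._maps[key] = _score_maps(self.section(w0, t), self.bank)
        return self._maps[key]

    def window(self, y_c: int) -> tuple[int, int] | None:
        """Slab window of section_thickness centered at y_c, or None if it
        would extend beyond the volume."""
        t = self.params.section_thickness
        w0 = y_c - t // 2
        if w0 < 0 or w0 + t > self.vol.shape[1]:
            return None
        return w0, t

    def next_marker(
        self, current: Sequence[float], sign: int = 1
    ) -> tuple[np.ndarray, float] | None:
        """Best placement over the candidate step distances, or None at the end.

        Candidates are compared on the normalized matched-filter score; ties
        prefer the smallest step distance.
        """
        cx, cy, cz = float(current[0]), float(current[1]), float(current[2])
        best: tuple[float, int, np.ndarray, KernelSpec, int] | None = None
        for d in self.params.step_candidates:
            y_c = int(round(cy)) + sign * d
            win = self.window(y_c)
            if win is None:
                continue
            v = axis_at(self.field, float(y_c))
            pred = (
                cx + sign * d * v[0] / v[1],
                cz + sign * d * v[2] / v[1],
            )
            r = min(self.params.search_radius_voxels * d / 10.0, self.params.displacement_cap)
            sel = _select(self.maps(*win), self.bank, pred, r)
            if sel is None:
                continue
            pos, k_idx, score = sel
            if best is None or score > best[0] + _TIE_TOL * max(1.0, abs(best[0])):
                best = (score, y_c, pos, self.bank.specs[k_idx], win[0])
        if best is None:
            return None
        score, y_c, pos, spec, w0 = best
        pos, score = _refine(self.section(w0, self.params.section_thickness), pos, spec, self.bank.R)
        return np.array([pos[0], float(y_c), pos[1]]), score


def next_marker(
    vol: DensityVolume,
    current: Sequence[float],
    field: AxisField,
    params: TraceParams,
    n_peaks: int,
) -> tuple[np.ndarray, float] | None:
    """Place the next marker downstream of ``current`` (see :class:`_Tracer`).

    Returns ``(marker, score)`` or ``None`` when every candidate slab would
    extend beyond the volume (normal termination).
    """
    nx, ny, nz = vol.shape
    if not (0 <= current[0] <= nx - 1 and 0 <= current[1] <= ny - 1 and 0 <= current[2] <= nz - 1):
        raise ValidationError(f"current point {tuple(current)} outside volume {vol.shape}")
    return _Tracer(vol, field, params, n_peaks).next_marker(current, sign=1)


def trace_bundle(
    vol: DensityVolume,
    seeds: SeedSet,
    field: AxisField,
    params: TraceParams,
    n_peaks: int = 7,
) -> BundleModel:
    """Trace one filament per seed through the volume.

    The first marker refines the seed in-plane on the seed slab; subsequent
    markers come from repeated next-marker placements in +y (and in -y when
    the seed slab is not at the volume edge).  Tracing is fully deterministic.
    """
    nx, ny, nz = vol.shape
    if not (0 <= seeds.y0 <= ny - 1):
        raise ValidationError(f"seed y0={seeds.y0} outside volume of length {ny}")
    for i, (x, z) in enumerate(seeds.points):
        if not (0 <= x <= nx - 1 and 0 <= z <= nz - 1):
            raise ValidationError(f"seed {i} at ({x}, {z}) outside volume cross-section")
    if len(seeds) > 1:
        from scipy.spatial.distance import pdist

        if pdist(seeds.points).min() < 2.0 * params.sigma_voxels:
            raise ValidationError(
                f"seed points closer than 2*sigma = {2 * params.sigma_voxels} voxels"
            )

    tracer = _Tracer(vol, field, params, n_peaks)
    t_seed = min(seeds.slab_thickness, ny)
    w0_seed = int(np.clip(seeds.y0 - t_seed // 2, 0, ny - t_seed))
    seed_maps = _score_maps(tracer.section(w0_seed, t_seed), tracer.bank)

    traces = []
    for i, (sx, sz) in enumerate(seeds.points):
        sel = _select(seed_maps, tracer.bank, (sx, sz), params.search_radius_voxels)
        if sel is None:
            raise ValidationError(
                f"seed {i} at ({sx}, {sz}): kernel support does not fit the section "
                "anywhere within the search radius"
            )
        pos, k_idx, _ = sel
        pos, _ = _refine(
            tracer.section(w0_seed, t_seed), pos, tracer.bank.specs[k_idx], tracer.bank.R
        )
        first = np.array([pos[0], float(seeds.y0), pos[1]])

        markers = [first]
        cur = first
        while (res := tracer.next_marker(cur, sign=1)) is not None:
            cur = res[0]
            markers.append(cur)
        if seeds.y0 > 0:
            cur = first
            while (res := tracer.next_marker(cur, sign=-1)) is not None:
                cur = res[0]
                markers.insert(0, cur)
        if len(markers) < 2:
            log.warning("seed %d produced a single marker; trace skipped", i)
            continue
        arr = np.asarray(markers)
        arr = arr[np.argsort(arr[:, 1], kind="stable")]
        traces.append(FilamentTrace(markers=arr, id=seeds.ids[i]))

    return BundleModel(
        traces=traces,
        provenance={
            "method": f"trace_{n_peaks}peak",
            "params": repr(params),
            "y0": seeds.y0,
            "n_seeds": len(seeds),
        },
    )


def seeds_from_model(model: BundleModel, y0: int, slab_thickness: int = 30) -> SeedSet:
    """Exact seeds at ``y0`` from a reference model (one per filament,
    interpolated along each trace); ids carry over for evaluation."""
    pts = np.array(
        [
            [
                np.interp(y0, t.markers[:, 1], t.markers[:, 0]),
                np.interp(y0, t.markers[:, 1], t.markers[:, 2]),
            ]
            for t in model.traces
        ]
    )
    return SeedSet(points=pts, y0=y0, slab_thickness=slab_thickness, ids=model.ids())


# ---------------------------------------------------------------------------
# seed file I/O (CSV: columns id,x,z; y0 and slab thickness in '#' header lines)
# ---------------------------------------------------------------------------


def write_seeds(seeds: SeedSet, path: str | Path) -> None:
    lines = [f"# y0={seeds.y0}", f"# slab_thickness={seeds.slab_thickness}", "id,x,z"]
    for fid, (x, z) in zip(seeds.ids, seeds.points):
        lines.append(f"{fid},{x:.9g},{z:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_seeds(path: str | Path) -> SeedSet:
    meta = {}
    rows = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            k, _, val = line.lstrip("# ").partition("=")
            meta[k.strip()] = val.strip()
            continue
        if header is None:
            header = [c.strip() for c in line.split(",")]
            continue
        rows.append(dict(zip(header, line.split(","))))
    if "y0" not in meta:
        raise ValidationError(f"{path}: seed file lacks '# y0=...' header line")
    if header is None or not {"x", "z"}.issubset(header):
        raise ValidationError(f"{path}: seed file needs columns x,z")
    pts = np.array([[float(r["x"]), float(r["z"])] for r in rows])
    ids = [r["id"] for r in rows] if "id" in (header or []) else None
    return SeedSet(
        points=pts,
        y0=int(meta["y0"]),
        slab_thickness=int(meta.get("slab_thickness", 30)),
        ids=ids,
    )
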