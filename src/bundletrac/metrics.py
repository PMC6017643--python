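"""Agreement between two filament models: the cross-distance and summaries.

The cross-distance of a test filament against a reference filament is the
mean, over the reference markers inside the common y-range, of the 3D
distance from each reference marker to the nearest point of the finely
interpolated test polyline.  It measures lateral disagreement between two
curves while ignoring longitudinal offset (markers outside the overlap are
excluded, and nearest points slide freely along the test curve).

``improvement(err_base, err_new)`` is the usual relative error reduction in
percent, used to compare tracing variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ValidationError
from .volume_io import BundleModel, FilamentTrace

__all__ = ["CrossDistanceReport", "cross_distance", "evaluate", "improvement"]

_DEFAULT_STEP = 0.1  # voxels of arc length between interpolated test points


@dataclass
class CrossDistanceReport:
    """Per-filament and bundle-level cross-distance summary.

    ``mean_Df`` is the unweighted mean of the per-filament values;
    ``n_within`` counts filaments with ``D_f <= threshold``.
    """

    per_filament: list[tuple[str, float, int]]
    threshold: float
    mean_Df: float = field(init=False)
    n_within: int = field(init=False)
    fraction_within: float = field(init=False)

    def __post_init__(self) -> None:
        dfs = np.array([d for _, d, _ in self.per_filament])
        if len(dfs) == 0:
            raise ValidationError("report needs at least one filament")
        self.mean_Df = float(dfs.mean())
        self.n_within = int(np.sum(dfs <= self.threshold))
        self.fraction_within = self.n_within / len(dfs)

    def to_dict(self) -> dict:
        return {
            "per_filament": [
                {"id": fid, "D_f": d, "n": n} for fid, d, n in self.per_filament
            ],
            "mean_Df": self.mean_Df,
            "threshold": self.threshold,
            "n_within": self.n_within,
            "fraction_within": self.fraction_within,
        }


def _interpolate_polyline(markers: np.ndarray, step: float) -> np.ndarray:
    """Points along the polyline at <= ``step``-voxel arc increments.

    The original vertices are always included, so consecutive samples lie on
    a single polyline segment and chords never cut corners.
    """
    seg = np.linalg.norm(np.diff(markers, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step)), 1)
    t = np.union1d(np.linspace(0.0, total, n + 1), s)
    return np.column_stack([np.interp(t, s, markers[:, c]) for c in range(3)])


def cross_distance(
    ref: FilamentTrace,
    test: FilamentTrace,
    step: float = _DEFAULT_STEP,
    mode: str = "3d",
) -> tuple[float, int]:
    """Average cross-distance ``D_f`` of ``test`` against ``ref`` and the
    number ``n`` of reference markers used.

    ``mode="3d"`` (default): nearest point on the interpolated test polyline
    in 3D Euclidean distance.  ``mode="planar"``: in-plane X-Z distance to
    the test curve evaluated at each reference marker's y (a sensitivity
    variant).  Reference markers outside the common y-range are excluded;
    fewer than two overlapping markers is an error.
    """
    y_lo = max(ref.markers[0, 1], test.markers[0, 1])
    y_hi = min(ref.markers[-1, 1], test.markers[-1, 1])
    sel = (ref.markers[:, 1] >= y_lo - 1e-9) & (ref.markers[:, 1] <= y_hi + 1e-9)
    P = ref.markers[sel]
    if len(P) < 2:
        raise ValidationError(
            f"traces {ref.id!r}/{test.id!r} overlap over {len(P)} reference markers; need >= 2"
        )
    if mode == "3d":
        dense = _interpolate_polyline(test.markers, step)
        _, idx = cKDTree(dense).query(P, k=1)
        # exact projection onto the polyline segments adjacent to the nearest
        # sample, removing the residual chord-sampling error
        dists = np.empty(len(P))
        for i, (p, j) in enumerate(zip(P, idx)):
            best = np.linalg.norm(p - dense[j])
            for a, b in ((j - 1, j), (j, j + 1)):
                if a < 0 or b >= len(dense):
                    continue
                seg = dense[b] - dense[a]
                L2 = seg @ seg
                if L2 == 0.0:
                    continue
                t = np.clip((p - dense[a]) @ seg / L2, 0.0, 1.0)
                best = min(best, float(np.linalg.norm(p - (dense[a] + t * seg))))
            dists[i] = best
    elif mode == "planar":
        tx = np.interp(P[:, 1], test.markers[:, 1], test.markers[:, 0])
        tz = np.interp(P[:, 1], test.markers[:, 1], test.markers[:, 2])
        dists = np.hypot(P[:, 0] - tx, P[:, 2] - tz)
    else:
        raise ValidationError(f"unknown mode {mode!r}; use '3d' or 'planar'")
    return float(np.mean(dists)), int(len(P))


def evaluate(
    ref: BundleModel,
    test: BundleModel,
    threshold: float = 3.0,
    mode: str = "3d",
) -> CrossDistanceReport:
    """Per-filament cross-distances of ``test`` against ``ref``, matched by id."""
    ref_ids, test_ids = set(ref.ids()), set(test.ids())
    if ref_ids != test_ids:
        raise ValidationError(
            f"filament id mismatch: only in ref {sorted(ref_ids - test_ids)}, "
            f"only in test {sorted(test_ids - ref_ids)}"
        )
    per = []
    for rt in ref.traces:
        d, n = cross_distance(rt, test.get(rt.id), mode=mode)
        per.append((rt.id, d, n))
    return CrossDistanceReport(per_filament=per, threshold=float(threshold))


def improvement(err_base: float, err_new: float) -> float:
    """Relative error reduction in percent: ``(base - new) / base * 100``."""
    if err_base <= 0:
        raise ValidationError(f"err_base must be > 0, got {err_base}")
    return (err_base - err_new) / err_base * 100.0
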