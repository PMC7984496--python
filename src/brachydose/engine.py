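"""TG-43 superposition dose engine.

Per-fraction dose at a point is the exact sum over dwells of
dose_rate * dwell_time / 3600; no approximation is made beyond the TG-43
factorization itself, so chunk sizes and evaluation order cannot change
the result.  Voxels closer than 1 mm to a dwell are evaluated at r = 1 mm
and counted (near-field cap; clinical TPSs are likewise not valid there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import VoxelGrid
from .implant import ImplantPlan
from .sources import SourceSpec, _dwell_rate_kernel

R_CAP_MM = 1.0


@dataclass
class DoseGrid:
    grid: VoxelGrid
    values_cgy: np.ndarray  # per fraction, grid.shape
    n_capped_voxels: int = 0

    def __post_init__(self):
        if self.values_cgy.shape != self.grid.shape:
            raise ValueError("dose array shape must match grid shape")
        if not np.all(np.isfinite(self.values_cgy)) or np.any(self.values_cgy < 0):
            raise ValueError("dose values must be finite and nonnegative")


def _dose_sum(points_mm: np.ndarray, dwell_pos: np.ndarray, dwell_axis: np.ndarray,
              times_s: np.ndarray, s_k: float, spec: SourceSpec,
              cap_mm: float = R_CAP_MM):
    """Exact superposition over dwells for an (N, 3) block of points.

    Returns (dose_cgy (N,), n_capped_points).
    """
    pts = np.asarray(points_mm, float)
    dose = np.zeros(pts.shape[0])
    cap_cm = cap_mm / 10.0
    capped = np.zeros(pts.shape[0], bool)
    for d in range(dwell_pos.shape[0]):
        t = times_s[d]
        if t == 0.0:
            continue
        rate, near = _dwell_rate_kernel(spec, dwell_pos[d], dwell_axis[d],
                                        s_k, pts, cap_cm=cap_cm)
        capped |= near
        dose += rate * t / 3600.0
    return dose, int(np.count_nonzero(capped))


def dose_at_points(plan: ImplantPlan, spec: SourceSpec, points_mm,
                   chunk: int = 200_000) -> np.ndarray:
    """Per-fraction dose (cGy) at arbitrary points, chunked superposition."""
    pts = np.atleast_2d(np.asarray(points_mm, float))
    pos, axes = plan.dwell_geometry
    out = np.empty(pts.shape[0])
    for lo in range(0, pts.shape[0], chunk):
        hi = min(lo + chunk, pts.shape[0])
        out[lo:hi], _ = _dose_sum(
            pts[lo:hi], pos, axes, plan.dwell_times_s,
            plan.air_kerma_strength_U, spec,
        )
    return out


def compute_dose_grid(plan: ImplantPlan, spec: SourceSpec, grid: VoxelGrid,
                      chunk: int = 200_000) -> DoseGrid:
    """Per-fraction dose on every voxel center of ``grid``."""
    pts = grid.voxel_centers()
    pos, axes = plan.dwell_geometry
    values = np.empty(pts.shape[0])
    n_capped = 0
    for lo in range(0, pts.shape[0], chunk):
        hi = min(lo + chunk, pts.shape[0])
        values[lo:hi], nc = _dose_sum(
            pts[lo:hi], pos, axes, plan.dwell_times_s,
            plan.air_kerma_strength_U, spec,
        )
        n_capped += nc
    return DoseGrid(grid=grid, values_cgy=values.reshape(grid.shape),
                    n_capped_voxels=n_capped)


def point_dose(plan: ImplantPlan, spec: SourceSpec, point_mm) -> float:
    """Per-fraction dose (cGy) at a single point."""
    return float(dose_at_points(plan, spec, np.atleast_2d(point_mm))[0])
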