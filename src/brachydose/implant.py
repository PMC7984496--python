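"""Catheter, dwell and implant-plan geometry.

Models the free-hand interstitial technique: rigid needles placed through
the open cavity in one or two planes at 1.5-2 cm triangular spacing, then
replaced by plastic catheters secured with skin buttons.  Also builds the
two-catheter slab-phantom plans used for the surface-dose experiments.

Coordinates are patient-space mm with the skin plane at z = 0 and tissue
at z > 0 (depth).  Catheters run along the y (cranio-caudal) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json
import math

import numpy as np

from .sources import DwellSource


class InfeasibleImplantError(ValueError):
    """Raised when the requested implant cannot honor the skin-depth rule."""


@dataclass(frozen=True)
class Catheter:
    """One implanted catheter.

    ``path_mm`` is the intratissue polyline (>= 2 points, distinct
    consecutive points).  ``button_positions_mm`` are the two skin securing
    points; they share the lateral (x, y) coordinates of the path endpoints
    and sit on the skin surface z = 0.
    """

    id: str
    path_mm: np.ndarray
    button_positions_mm: np.ndarray | None = None

    def __post_init__(self):
        path = np.atleast_2d(np.asarray(self.path_mm, float))
        if path.shape[0] < 2 or path.shape[1] != 3:
            raise ValueError("catheter path needs >= 2 points of dim 3")
        if np.any(np.linalg.norm(np.diff(path, axis=0), axis=1) < 1e-12):
            raise ValueError("consecutive path points must be distinct")
        object.__setattr__(self, "path_mm", path)
        if self.button_positions_mm is None:
            buttons = path[[0, -1]].copy()
            buttons[:, 2] = 0.0
            object.__setattr__(self, "button_positions_mm", buttons)
        else:
            buttons = np.asarray(self.button_positions_mm, float)
            if buttons.shape != (2, 3):
                raise ValueError("exactly two button positions required")
            ends = path[[0, -1], :2]
            if np.max(np.abs(buttons[:, :2] - ends)) > 1e-6:
                raise ValueError("buttons must sit over the path endpoints")
            object.__setattr__(self, "button_positions_mm", buttons)

    @property
    def arc_length_mm(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.path_mm, axis=0), axis=1)))


@dataclass(frozen=True)
class FreehandTemplate:
    """Free-hand implant template: one or two parallel planes of catheters
    at triangular spacing."""

    n_planes: int = 2
    spacing_cm: float = 2.0
    plane_separation_cm: float | None = None  # default: equilateral rows
    triangular_offset: float = 0.5
    min_skin_depth_mm: float = 5.0
    allow_nonstandard_spacing: bool = False

    def __post_init__(self):
        if self.n_planes not in (1, 2):
            raise ValueError("n_planes must be 1 or 2")
        if not self.allow_nonstandard_spacing and not (1.5 <= self.spacing_cm <= 2.0):
            raise ValueError("catheter spacing must lie in [1.5, 2.0] cm")
        if self.min_skin_depth_mm < 5.0:
            raise ValueError("minimum skin depth is 5 mm")

    @property
    def plane_sep_mm(self) -> float:
        if self.plane_separation_cm is not None:
            return self.plane_separation_cm * 10.0
        return self.spacing_cm * 10.0 * math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class PhantomSetup:
    """Two-catheter slab-phantom experiment geometry."""

    variant: str = "surface_points"  # or "perpendicular_film"
    catheter_depth_mm: float = 5.0
    catheter_separation_cm: float = 2.0
    film_plane_depth_cm: float = 2.0
    catheter_length_mm: float = 100.0

    def __post_init__(self):
        if self.variant not in ("surface_points", "perpendicular_film"):
            raise ValueError(f"unknown phantom variant {self.variant!r}")
        if self.catheter_depth_mm <= 0 or self.catheter_separation_cm <= 0:
            raise ValueError("depth and separation must be positive")


@dataclass
class ImplantPlan:
    """Catheters + dwell pattern + prescription; the dose engine's input."""

    catheters: list
    dwell_step_mm: float = 5.0
    dwell_retraction_mm: float = 5.0
    dwell_times_s: np.ndarray | None = None
    air_kerma_strength_U: float = 40800.0  # ~10 Ci Ir-192
    prescription_cgy_per_fraction: float = 340.0
    n_fractions: int = 10
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dwell_step_mm <= 0:
            raise ValueError("dwell step must be > 0")
        if self.prescription_cgy_per_fraction <= 0:
            raise ValueError("prescription must be > 0")
        if self.dwell_times_s is None:
            self.dwell_times_s = np.ones(self.n_dwells)
        self.dwell_times_s = np.asarray(self.dwell_times_s, float)
        if self.dwell_times_s.shape != (self.n_dwells,):
            raise ValueError("one dwell time per dwell position required")
        if np.any(self.dwell_times_s < 0):
            raise ValueError("dwell times must be >= 0")

    @property
    def dwell_geometry(self):
        """(positions (N,3) mm, axes (N,3)) over all catheters, in order."""
        pos, axes = [], []
        for cath in self.catheters:
            p, a = dwell_positions(cath, self.dwell_step_mm, self.dwell_retraction_mm)
            pos.append(p)
            axes.append(a)
        return np.vstack(pos), np.vstack(axes)

    @property
    def n_dwells(self) -> int:
        return sum(
            _n_dwells(c.arc_length_mm, self.dwell_step_mm, self.dwell_retraction_mm)
            for c in self.catheters
        )

    def dwell_sources(self):
        pos, axes = self.dwell_geometry
        return [
            DwellSource(pos[i], axes[i], self.air_kerma_strength_U)
            for i in range(pos.shape[0])
        ]

    def with_times(self, times_s) -> "ImplantPlan":
        return ImplantPlan(
            catheters=self.catheters,
            dwell_step_mm=self.dwell_step_mm,
            dwell_retraction_mm=self.dwell_retraction_mm,
            dwell_times_s=np.asarray(times_s, float),
            air_kerma_strength_U=self.air_kerma_strength_U,
            prescription_cgy_per_fraction=self.prescription_cgy_per_fraction,
            n_fractions=self.n_fractions,
            metadata=dict(self.metadata),
        )

    @property
    def total_dose_cgy(self) -> float:
        return self.prescription_cgy_per_fraction * self.n_fractions


def _n_dwells(arclength: float, step: float, retraction: float) -> int:
    usable = arclength - 2.0 * retraction
    if usable <= 0:
        raise ValueError("catheter shorter than twice the retraction")
    return int(math.floor(usable / step + 1e-9)) + 1


def dwell_positions(catheter: Catheter, step_mm: float, retraction_mm: float = 0.0):
    """Equally spaced (by arc length) dwell positions and local tangents.

    Count = floor((arclength - 2*retraction)/step) + 1, centred placement
    starting at ``retraction`` from the path start.
    """
    if step_mm <= 0:
        raise ValueError("dwell step must be > 0")
    path = catheter.path_mm
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = _n_dwells(total, step_mm, retraction_mm)
    s = retraction_mm + step_mm * np.arange(n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pos = path[idx] + frac[:, None] * seg[idx]
    tangents = seg[idx] / seg_len[idx][:, None]
    return pos, tangents


def catheter_count_1d(extent_mm: float, pitch_mm: float) -> int:
    """Smallest number of equally pitched lines, centred on the interval,
    covering a 1D extent so no point is farther than pitch/2 from a line."""
    if extent_mm <= 0:
        return 1
    return max(1, int(math.ceil(extent_mm / pitch_mm - 1e-9)))


def generate_freehand_implant(
    cavity_center_mm,
    cavity_radius_mm: float,
    template: FreehandTemplate,
    margin_mm: float = 20.0,
) -> list:
    """Place straight parallel catheters (along y) covering the cavity plus
    margin footprint at the template's triangular spacing.

    The implant planes straddle the cavity centre depth, clamped so every
    catheter stays at least ``min_skin_depth_mm`` below the skin (z = 0).
    Raises :class:`InfeasibleImplantError` when the cavity is too shallow
    for that rule.
    """
    c = np.asarray(cavity_center_mm, float)
    spacing = template.spacing_cm * 10.0
    min_depth = template.min_skin_depth_mm
    if c[2] - cavity_radius_mm < min_depth:
        raise InfeasibleImplantError(
            f"cavity top at {c[2] - cavity_radius_mm:.1f} mm is shallower than "
            f"the {min_depth:.0f} mm minimum catheter depth"
        )
    R = cavity_radius_mm + margin_mm  # footprint radius to tile (x direction)
    half_span_y = cavity_radius_mm + margin_mm  # axial span: cavity + 2 cm

    if template.n_planes == 1:
        plane_depths = [max(c[2], min_depth)]
    else:
        sep = template.plane_sep_mm
        z1 = max(c[2] - sep / 2.0, min_depth)
        plane_depths = [z1, z1 + sep]

    catheters = []
    k = 0
    for p, z in enumerate(plane_depths):
        n = catheter_count_1d(2.0 * R, spacing)
        offset = (p % 2) * template.triangular_offset * spacing
        xs = c[0] + offset + (np.arange(n) - (n - 1) / 2.0) * spacing
        for x in xs:
            path = np.array(
                [[x, c[1] - half_span_y, z], [x, c[1] + half_span_y, z]]
            )
            catheters.append(Catheter(id=f"cath{k:02d}", path_mm=path))
            k += 1
    return catheters


def build_phantom_plan(setup: PhantomSetup, dwell_step_mm: float = 5.0,
                       air_kerma_strength_U: float = 40800.0) -> ImplantPlan:
    """Two parallel straight catheters at the setup depth, 2 cm apart,
    uniform dwell times."""
    depth = (
        setup.film_plane_depth_cm * 10.0
        if setup.variant == "perpendicular_film"
        else setup.catheter_depth_mm
    )
    half_sep = setup.catheter_separation_cm * 10.0 / 2.0
    half_len = setup.catheter_length_mm / 2.0
    caths = []
    for i, x in enumerate((-half_sep, half_sep)):
        path = np.array([[x, -half_len, depth], [x, half_len, depth]])
        caths.append(Catheter(id=f"phantom{i}", path_mm=path))
    return ImplantPlan(
        catheters=caths,
        dwell_step_mm=dwell_step_mm,
        dwell_retraction_mm=0.0,
        air_kerma_strength_U=air_kerma_strength_U,
        metadata={"phantom_variant": setup.variant, "depth_mm": depth},
    )


# ---------------------------------------------------------------------------
# Plan serialization (dwell-table CSV + plan JSON)


def save_plan(plan: ImplantPlan, plan_json, dwell_csv) -> None:
    import pandas as pd

    rows = []
    i = 0
    for cath in plan.catheters:
        pos, tan = dwell_positions(cath, plan.dwell_step_mm, plan.dwell_retraction_mm)
        for j in range(pos.shape[0]):
            rows.append(
                dict(
                    catheter_id=cath.id,
                    dwell_index=j,
                    x_mm=pos[j, 0], y_mm=pos[j, 1], z_mm=pos[j, 2],
                    tx=tan[j, 0], ty=tan[j, 1], tz=tan[j, 2],
                    time_s=plan.dwell_times_s[i],
                )
            )
            i += 1
    pd.DataFrame(rows).to_csv(dwell_csv, index=False)
    meta = {
        "dwell_step_mm": plan.dwell_step_mm,
        "dwell_retraction_mm": plan.dwell_retraction_mm,
        "air_kerma_strength_U": plan.air_kerma_strength_U,
        "prescription_cgy_per_fraction": plan.prescription_cgy_per_fraction,
        "n_fractions": plan.n_fractions,
        "dwell_table": str(dwell_csv),
        "catheters": [
            {"id": c.id, "path_mm": c.path_mm.tolist(),
             "buttons_mm": c.button_positions_mm.tolist()}
            for c in plan.catheters
        ],
        "metadata": plan.metadata,
    }
    Path(plan_json).write_text(json.dumps(meta, indent=2))


def load_plan(plan_json) -> ImplantPlan:
    import pandas as pd

    meta = json.loads(Path(plan_json).read_text())
    caths = [
        Catheter(
            id=c["id"],
            path_mm=np.asarray(c["path_mm"]),
            button_positions_mm=np.asarray(c["buttons_mm"]),
        )
        for c in meta["catheters"]
    ]
    times = pd.read_csv(meta["dwell_table"])["time_s"].to_numpy()
    return ImplantPlan(
        catheters=caths,
        dwell_step_mm=meta["dwell_step_mm"],
        dwell_retraction_mm=meta["dwell_retraction_mm"],
        dwell_times_s=times,
        air_kerma_strength_U=meta["air_kerma_strength_U"],
        prescription_cgy_per_fraction=meta["prescription_cgy_per_fraction"],
        n_fractions=meta["n_fractions"],
        metadata=meta.get("metadata", {}),
    )
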