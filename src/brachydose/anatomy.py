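"""Voxelized patient/phantom geometry and structure construction.

Axis convention: x lateral, y cranio-caudal (the CT slice direction,
2.5 mm), z depth with the skin surface at z = 0 and tissue at z > 0.
Voxel-center convention: the center of voxel (i, j, k) is
origin + (i, j, k) * spacing.

The study-specific skin region is a quadrilateral footprint on the skin:
short sides at the outermost catheter-button edges along the catheter
direction, long sides parallel to the outermost catheters' skin
projections displaced outward by 1 cm, extruded to 3 mm depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class VoxelGrid:
    """Regular grid in patient space (mm)."""

    origin_mm: tuple
    spacing_mm: tuple = (1.0, 2.5, 1.0)
    shape: tuple = (0, 0, 0)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm) or any(n <= 0 for n in self.shape):
            raise ValueError("spacing and shape must be positive")

    @property
    def voxel_volume_cc(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz / 1000.0

    def axes(self):
        return tuple(
            self.origin_mm[d] + self.spacing_mm[d] * np.arange(self.shape[d])
            for d in range(3)
        )

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) array of voxel centers in C order."""
        ax, ay, az = self.axes()
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def mask_volume_cc(self, mask) -> float:
        return float(np.count_nonzero(mask)) * self.voxel_volume_cc


@dataclass(frozen=True)
class SkinRegionSpec:
    """Parameters of the TPS skin-dose evaluation region."""

    lateral_margin_mm: float = 10.0
    depth_mm: float = 3.0


@dataclass
class StructureSet:
    """Boolean masks on a common grid.  tumor_bed ⊆ CTV ⊆ PTV must hold."""

    grid: VoxelGrid
    masks: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    REQUIRED_NESTING = (("tumor_bed", "ctv"), ("ctv", "ptv"))

    def __setitem__(self, name, mask):
        mask = np.asarray(mask, bool)
        if mask.shape != self.grid.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != grid {self.grid.shape}")
        self.masks[name] = mask

    def __getitem__(self, name):
        return self.masks[name]

    def __contains__(self, name):
        return name in self.masks

    def validate(self):
        for inner, outer in self.REQUIRED_NESTING:
            if inner in self.masks and outer in self.masks:
                if np.any(self.masks[inner] & ~self.masks[outer]):
                    raise ValueError(f"nesting violated: {inner} ⊄ {outer}")
        if "skin_region" in self.masks:
            z = self.grid.axes()[2]
            bad = self.masks["skin_region"] & (z[None, None, :] > 3.0 + 1e-9)
            if np.any(bad):
                raise ValueError("skin region extends deeper than 3 mm")
        return self

    def volume_cc(self, name) -> float:
        return self.grid.mask_volume_cc(self.masks[name])


def expand_margin(mask, margin_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Euclidean isotropic expansion: all voxels whose center lies within
    ``margin_mm`` of the input voxel set."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot expand an empty mask")
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=grid.spacing_mm)
    return dist <= margin_mm + 1e-9


def sphere_mask(grid: VoxelGrid, center_mm, radius_mm: float) -> np.ndarray:
    ax, ay, az = grid.axes()
    c = np.asarray(center_mm, float)
    d2 = (
        (ax[:, None, None] - c[0]) ** 2
        + (ay[None, :, None] - c[1]) ** 2
        + (az[None, None, :] - c[2]) ** 2
    )
    return d2 <= radius_mm**2


def ellipsoid_mask(grid: VoxelGrid, center_mm, semiaxes_mm) -> np.ndarray:
    ax, ay, az = grid.axes()
    c = np.asarray(center_mm, float)
    s = np.asarray(semiaxes_mm, float)
    q = (
        ((ax[:, None, None] - c[0]) / s[0]) ** 2
        + ((ay[None, :, None] - c[1]) / s[1]) ** 2
        + ((az[None, None, :] - c[2]) / s[2]) ** 2
    )
    return q <= 1.0


def slab_mask(grid: VoxelGrid, z_min_mm: float, z_max_mm: float) -> np.ndarray:
    z = grid.axes()[2]
    inz = (z >= z_min_mm - 1e-9) & (z < z_max_mm - 1e-9)
    out = np.zeros(grid.shape, bool)
    out[:, :, inz] = True
    return out


def build_skin_region(catheters, grid: VoxelGrid,
                      spec: SkinRegionSpec = SkinRegionSpec()) -> np.ndarray:
    """Quadrilateral skin region over the implant, extruded to 3 mm depth.

    Catheters are assumed to run along y (their skin projections are lines
    of constant x); a single catheter degenerates to a strip 2 cm wide
    centred on its projection.
    """
    if not catheters:
        raise ValueError("at least one catheter required")
    buttons = np.vstack([c.button_positions_mm for c in catheters])
    if np.any(np.abs(buttons[:, 2]) > 1e-6):
        raise ValueError("catheter buttons must lie on the skin surface z=0")
    x_lo = buttons[:, 0].min() - spec.lateral_margin_mm
    x_hi = buttons[:, 0].max() + spec.lateral_margin_mm
    y_lo = buttons[:, 1].min()
    y_hi = buttons[:, 1].max()
    ax, ay, az = grid.axes()
    inx = (ax >= x_lo - 1e-9) & (ax <= x_hi + 1e-9)
    iny = (ay >= y_lo - 1e-9) & (ay <= y_hi + 1e-9)
    inz = (az >= -1e-9) & (az <= spec.depth_mm + 1e-9)
    return inx[:, None, None] & iny[None, :, None] & inz[None, None, :]


def skin_region_footprint(catheters, spec: SkinRegionSpec = SkinRegionSpec()):
    """(x_lo, x_hi, y_lo, y_hi) of the skin-region footprint in mm."""
    buttons = np.vstack([c.button_positions_mm for c in catheters])
    return (
        buttons[:, 0].min() - spec.lateral_margin_mm,
        buttons[:, 0].max() + spec.lateral_margin_mm,
        buttons[:, 1].min(),
        buttons[:, 1].max(),
    )


def involved_ribs(catheters, rib_mask, grid: VoxelGrid,
                  spec: SkinRegionSpec = SkinRegionSpec()) -> np.ndarray:
    """Rib volume just beneath the skin region: intersection of the rib
    structure with the vertical prism under the skin-region footprint."""
    x_lo, x_hi, y_lo, y_hi = skin_region_footprint(catheters, spec)
    ax, ay, _ = grid.axes()
    inx = (ax >= x_lo - 1e-9) & (ax <= x_hi + 1e-9)
    iny = (ay >= y_lo - 1e-9) & (ay <= y_hi + 1e-9)
    prism = inx[:, None, None] & iny[None, :, None]
    return np.asarray(rib_mask, bool) & prism


def skin_measurement_point(scar_polyline_mm, offset_mm: float = 20.0,
                           side: float = +1.0) -> np.ndarray:
    """Film measurement point: on the skin, ``offset_mm`` from the scar
    midpoint, perpendicular to the scar, on the configured side."""
    scar = np.atleast_2d(np.asarray(scar_polyline_mm, float))
    seg = np.diff(scar, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    if total <= 0:
        raise ValueError("scar must have positive length")
    # arc-length midpoint
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    i = int(np.clip(np.searchsorted(cum, total / 2.0, side="right") - 1, 0,
                    len(seg_len) - 1))
    frac = (total / 2.0 - cum[i]) / seg_len[i]
    mid = scar[i] + frac * seg[i]
    tangent = seg[i] / seg_len[i]
    normal = np.array([-tangent[1], tangent[0], 0.0])
    n = np.linalg.norm(normal)
    if n < 1e-12:  # scar along x-degenerate normal; fall back to +y
        normal = np.array([0.0, 1.0, 0.0])
        n = 1.0
    point = mid + side * offset_mm * normal / n
    point[2] = 0.0
    return point
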