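"""Synthetic patient cohort generator.

Emulates the study population (17 early-breast-cancer patients treated
with free-hand two-plane interstitial implants, 340 cGy x 10) so the whole
pipeline runs end-to-end without patient data:

* anatomy — a supine-flattened breast (half-ellipsoid against the skin
  plane z = 0) on a 2 cm chest slab whose first 5 mm are rib, with lung and
  heart as half-spaces behind the slab;
* a lumpectomy cavity at a drawn depth, CTV = cavity + 2 cm, PTV = CTV +
  0.5 cm, both cropped to breast tissue and to >= 5 mm below the skin;
* a free-hand two-plane implant, geometrically weighted dwell times
  rescaled to the 95%/95% coverage rule;
* an emulated film measurement: the TPS skin dose (D50% of the skin
  region) reduced by a depth-dependent backscatter deficit (logistic in
  the shallowest catheter depth) times multiplicative lognormal film noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import anatomy as ana
from . import engine, metrics as met, optimize as opt
from .implant import FreehandTemplate, ImplantPlan, generate_freehand_implant
from .sources import SourceSpec, generic_ir192_source


def logistic_deficit(depth_mm, asymptote: float = 0.35,
                     midpoint_mm: float = 7.5, scale_mm: float = 2.5):
    """Fractional backscatter deficit vs shallowest-catheter depth."""
    d = np.asarray(depth_mm, float)
    out = asymptote / (1.0 + np.exp(-(d - midpoint_mm) / scale_mm))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CohortSpec:
    """Distributions defining the synthetic study population."""

    n_patients: int = 17
    seed: int = 0
    # breast half-ellipsoid: lateral radius and depth (mm), lognormal
    breast_radius_log_mm: tuple = (np.log(60.0), 0.12)
    breast_thickness_log_mm: tuple = (np.log(32.0), 0.13)
    # lumpectomy cavity volume (cc), lognormal — sets the PTV span
    cavity_volume_log_cc: tuple = (np.log(3.0), 0.7)
    prescription_cgy: float = 340.0
    n_fractions: int = 10
    spacing_range_cm: tuple = (1.5, 2.0)
    film_noise_sigma: float = 0.03
    deficit_asymptote: float = 0.35
    deficit_midpoint_mm: float = 7.5
    deficit_scale_mm: float = 2.5
    grid_spacing_mm: tuple = (2.5, 2.5, 2.5)
    max_rejections: int = 200

    def deficit(self, depth_mm):
        return logistic_deficit(depth_mm, self.deficit_asymptote,
                                self.deficit_midpoint_mm, self.deficit_scale_mm)


@dataclass
class CaseGeometry:
    """One patient's geometric draw (all mm)."""

    breast_radius_mm: float
    breast_thickness_mm: float
    cavity_radius_mm: float
    cavity_depth_mm: float
    spacing_cm: float
    n_rejections: int = 0


@dataclass
class SyntheticCase:
    case_id: int
    geometry: CaseGeometry
    structures: ana.StructureSet
    plan: ImplantPlan | None
    metrics: dict | None
    shallow_depth_mm: float
    tps_skin_dose_cgy: float | None
    measured_skin_dose_cgy: float | None
    overestimation_pct: float | None
    provenance: dict = field(default_factory=dict)

    @property
    def v_ptv_cc(self) -> float:
        return self.structures.volume_cc("ptv")


def draw_geometry(rng: np.random.Generator, spec: CohortSpec) -> CaseGeometry:
    """Rejection-sample one feasible patient geometry."""
    rej = 0
    while True:
        r_lat = float(np.clip(rng.lognormal(*spec.breast_radius_log_mm), 45.0, 80.0))
        thick = float(np.clip(rng.lognormal(*spec.breast_thickness_log_mm), 26.0, 42.0))
        vol = float(np.clip(rng.lognormal(*spec.cavity_volume_log_cc), 0.8, 8.0))
        r_cav = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        lo, hi = r_cav + 7.0, thick - r_cav - 5.0
        spacing = float(rng.uniform(*spec.spacing_range_cm))
        if hi > lo:
            depth = float(rng.uniform(lo, hi))
            return CaseGeometry(r_lat, thick, r_cav, depth, spacing, rej)
        rej += 1
        if rej > spec.max_rejections:
            raise RuntimeError("could not draw a feasible patient geometry")


def build_case_anatomy(geom: CaseGeometry, catheters,
                       grid_spacing_mm=(2.5, 2.5, 2.5)) -> ana.StructureSet:
    """Voxelize one patient: breast, targets (cropped to tissue and to
    >= 5 mm depth), skin region, ribs/lung/heart layers."""
    sx, sy, sz = grid_spacing_mm
    half_xy = geom.breast_radius_mm + 25.0
    z_max = geom.breast_thickness_mm + 35.0  # breast + chest slab + lung/heart faces
    shape = (
        int(np.ceil(2 * half_xy / sx)),
        int(np.ceil(2 * half_xy / sy)),
        int(np.ceil(z_max / sz)),
    )
    grid = ana.VoxelGrid(origin_mm=(-half_xy, -half_xy, 0.0),
                         spacing_mm=grid_spacing_mm, shape=shape)
    T = geom.breast_thickness_mm
    breast = ana.ellipsoid_mask(
        grid, (0.0, 0.0, 0.0),
        (geom.breast_radius_mm, geom.breast_radius_mm, T),
    )
    cavity = ana.sphere_mask(grid, (0.0, 0.0, geom.cavity_depth_mm),
                             geom.cavity_radius_mm) & breast
    deep_enough = ana.slab_mask(grid, 5.0, z_max + sz)
    ctv_raw = ana.expand_margin(cavity, 20.0, grid)
    ctv = ctv_raw & breast & deep_enough
    ptv_raw = ana.expand_margin(ctv, 5.0, grid)
    ptv = ptv_raw & breast & deep_enough

    ribs = ana.slab_mask(grid, T, T + 5.0)
    lung = ana.slab_mask(grid, T + 20.0, z_max + sz)
    heart = lung.copy()
    heart[grid.axes()[0] >= 0.0, :, :] = False  # medial half, deeper offset
    heart &= ana.slab_mask(grid, T + 30.0, z_max + sz)
    lung &= ~heart

    ss = ana.StructureSet(grid=grid)
    ss["tumor_bed"] = cavity
    ss["ctv"] = ctv
    ss["ptv"] = ptv
    ss["ipsilateral_breast"] = breast
    ss["involved_ribs"] = ana.involved_ribs(catheters, ribs, grid)
    ss["ipsilateral_lung"] = lung
    ss["heart"] = heart
    ss["skin_region"] = ana.build_skin_region(catheters, grid)
    ss.metadata["ctv_cropped_fraction"] = 1.0 - np.count_nonzero(ctv) / max(
        np.count_nonzero(ctv_raw), 1
    )
    ss.validate()
    return ss


def oar_point_sets(geom: CaseGeometry, catheters):
    """Evaluation points for OARs that outgrow or outresolve the main grid.

    Lung and heart extend 10 cm behind the chest slab and are sampled at
    5 mm; the involved-rib layer is sampled at 2.5 mm inside the prism
    under the skin-region footprint.  Returns name -> (points, voxel cc).
    """
    T = geom.breast_thickness_mm
    half_xy = geom.breast_radius_mm + 25.0

    def _points(xs, ys, zs):
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    s = 5.0
    xs = np.arange(-half_xy, half_xy, s)
    ys = np.arange(-half_xy, half_xy, s)
    z_lung = np.arange(T + 20.0, T + 120.0, s)
    lung_pts = _points(xs, ys, z_lung)
    heart_sel = (lung_pts[:, 0] < 0.0) & (lung_pts[:, 2] >= T + 30.0)
    out = {
        "ipsilateral_lung": (lung_pts[~heart_sel], s**3 / 1000.0),
        "heart": (lung_pts[heart_sel], s**3 / 1000.0),
    }
    x_lo, x_hi, y_lo, y_hi = ana.skin_region_footprint(catheters)
    r = 2.5
    rib_pts = _points(np.arange(x_lo, x_hi + 1e-9, r),
                      np.arange(y_lo, y_hi + 1e-9, r),
                      np.arange(T + r / 2, T + 5.0, r))
    out["involved_ribs"] = (rib_pts, r**3 / 1000.0)
    return out


def skin_fine_grid(catheters, spacing_mm=(1.0, 2.5, 1.0),
                   depth_mm: float = 3.0) -> ana.VoxelGrid:
    """Fine voxel grid restricted to the skin-region box (the 3 mm region is
    thin, so the TPS skin DVH is evaluated at 1 mm depth resolution)."""
    x_lo, x_hi, y_lo, y_hi = ana.skin_region_footprint(catheters)
    sx, sy, sz = spacing_mm
    shape = (
        max(int(np.floor((x_hi - x_lo) / sx)) + 1, 1),
        max(int(np.floor((y_hi - y_lo) / sy)) + 1, 1),
        max(int(np.floor(depth_mm / sz)), 1),
    )
    return ana.VoxelGrid(origin_mm=(x_lo, y_lo, sz / 2.0),
                         spacing_mm=spacing_mm, shape=shape)


def emulate_film_measurement(tps_skin_dose_cgy: float, shallow_depth_mm: float,
                             spec: CohortSpec, rng: np.random.Generator) -> float:
    """Film-like measured dose: TPS dose x (1 − deficit(depth)) x noise.

    Noise is multiplicative lognormal with mean 1 (film dosimetry error is
    multiplicative); sigma = ``spec.film_noise_sigma``.
    """
    if tps_skin_dose_cgy <= 0:
        raise ValueError("TPS skin dose must be > 0")
    deficit = spec.deficit(shallow_depth_mm)
    s = spec.film_noise_sigma
    noise = float(np.exp(rng.normal(-0.5 * s * s, s))) if s > 0 else 1.0
    return tps_skin_dose_cgy * (1.0 - deficit) * noise


def generate_case(case_id: int, rng: np.random.Generator, spec: CohortSpec,
                  source: SourceSpec, compute_dose: bool = True) -> SyntheticCase:
    geom = draw_geometry(rng, spec)
    # 7 mm plane floor: clinicians keep a margin beyond the 5 mm hard rule
    template = FreehandTemplate(n_planes=2, spacing_cm=geom.spacing_cm,
                                min_skin_depth_mm=7.0)
    # tile the PTV footprint (cavity + 2.5 cm) so coverage is achievable
    catheters = generate_freehand_implant(
        (0.0, 0.0, geom.cavity_depth_mm), geom.cavity_radius_mm, template,
        margin_mm=25.0,
    )
    structures = build_case_anatomy(geom, catheters, spec.grid_spacing_mm)
    shallow = min(float(c.path_mm[:, 2].min()) for c in catheters)
    plan = ImplantPlan(
        catheters=catheters,
        prescription_cgy_per_fraction=spec.prescription_cgy,
        n_fractions=spec.n_fractions,
        metadata={"case_id": case_id},
    )

    case = SyntheticCase(
        case_id=case_id, geometry=geom, structures=structures, plan=plan,
        metrics=None, shallow_depth_mm=shallow, tps_skin_dose_cgy=None,
        measured_skin_dose_cgy=None, overestimation_pct=None,
        provenance={"spec_seed": spec.seed, "case_id": case_id,
                    "n_rejections": geom.n_rejections,
                    "source": source.name},
    )
    if not compute_dose:
        # keep the film-noise draw count stable between modes
        rng.normal()
        return case

    grid = structures.grid
    plan, info = opt.optimize_plan(plan, source, structures["ptv"], grid)
    dose = engine.compute_dose_grid(plan, source, grid)
    fine = skin_fine_grid(catheters)
    overrides = {
        "skin_region": (
            engine.dose_at_points(plan, source, fine.voxel_centers()),
            fine.voxel_volume_cc,
        ),
    }
    for name, (pts, voxcc) in oar_point_sets(geom, catheters).items():
        overrides[name] = (engine.dose_at_points(plan, source, pts), voxcc)
    m = met.compute_plan_metrics(dose, structures, spec.prescription_cgy,
                                 oar_dose_overrides=overrides)

    # hard OAR limits cap the coverage normalization (dose is linear in the
    # global time scale, so no re-superposition is needed)
    cap = opt.oar_scale_cap(m, spec.prescription_cgy)
    # nontarget-breast V90% < 10% of volume <=> its 90th dose percentile
    # stays below 0.9 PD, which also converts to a scale bound
    dn = dose.values_cgy[structures["ipsilateral_breast"] & ~structures["ptv"]]
    q90 = float(np.percentile(dn, 90.0))
    if q90 > 0:
        cap = min(cap, 0.9 * spec.prescription_cgy / q90)
    if cap < 1.0:
        cap *= 0.995  # margin for DVH re-binning after the rescale
        plan = plan.with_times(plan.dwell_times_s * cap)
        dose = engine.DoseGrid(dose.grid, dose.values_cgy * cap,
                               dose.n_capped_voxels)
        overrides = {k: (v * cap, vv) for k, (v, vv) in overrides.items()}
        m = met.compute_plan_metrics(dose, structures, spec.prescription_cgy,
                                     oar_dose_overrides=overrides)
    info = {**info, "oar_cap_scale": min(cap, 1.0)}
    tps_skin = m["skin_d50pct_cgy"]
    measured = emulate_film_measurement(tps_skin, shallow, spec, rng)

    case.plan = plan
    case.metrics = m
    case.tps_skin_dose_cgy = tps_skin
    case.measured_skin_dose_cgy = measured
    case.overestimation_pct = met.overestimation_ratio(tps_skin, measured)
    case.provenance.update(optimization=info)
    return case


def generate_cohort(spec: CohortSpec, source: SourceSpec | None = None,
                    compute_dose: bool = True) -> list:
    """Deterministic cohort: same spec (incl. seed) -> identical cases."""
    if source is None:
        source = generic_ir192_source()
    cases = []
    for i, child in enumerate(np.random.SeedSequence(spec.seed).spawn(spec.n_patients)):
        rng = np.random.default_rng(child)
        cases.append(generate_case(i, rng, spec, source, compute_dose))
    return cases


def cohort_frame(cases) -> pd.DataFrame:
    """Per-case metric table (one row per patient)."""
    rows = []
    for c in cases:
        row = {"case_id": c.case_id, "v_ptv_cc": c.v_ptv_cc,
               "shallow_depth_mm": c.shallow_depth_mm}
        if c.metrics is not None:
            row.update(c.metrics)
            row["tps_skin_d50_cgy"] = c.tps_skin_dose_cgy
            row["measured_skin_cgy"] = c.measured_skin_dose_cgy
            row["overestimation_pct"] = c.overestimation_pct
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Deficit-model parameter recovery


def simulate_film_ratios(spec: CohortSpec, seed: int):
    """(depths_mm, overestimation fractions) for one cohort replicate.

    The overestimation ratio 1 − (1 − deficit) * noise does not involve the
    absolute TPS dose, so replicates draw implant depths and film noise
    through the same generator distributions without re-running the dose
    engine.
    """
    rep = CohortSpec(**{**asdict(spec), "seed": seed})
    depths = []
    ratios = []
    for child in np.random.SeedSequence(rep.seed).spawn(rep.n_patients):
        rng = np.random.default_rng(child)
        geom = draw_geometry(rng, rep)
        template = FreehandTemplate(n_planes=2, spacing_cm=geom.spacing_cm)
        caths = generate_freehand_implant(
            (0.0, 0.0, geom.cavity_depth_mm), geom.cavity_radius_mm, template
        )
        shallow = min(float(c.path_mm[:, 2].min()) for c in caths)
        measured = emulate_film_measurement(100.0, shallow, rep, rng)
        depths.append(shallow)
        ratios.append(1.0 - measured / 100.0)
    return np.asarray(depths), np.asarray(ratios)


def fit_deficit_asymptote(depths_mm, ratios, midpoint_mm: float = 7.5,
                          scale_mm: float = 2.5) -> float:
    """Least-squares asymptote of the logistic deficit model given its shape:
    ratio_i ≈ A * logistic(depth_i) => closed-form A."""
    g = logistic_deficit(np.asarray(depths_mm, float), 1.0, midpoint_mm, scale_mm)
    r = np.asarray(ratios, float)
    denom = float(g @ g)
    if denom <= 0:
        raise ValueError("degenerate depth design")
    return float(g @ r) / denom
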