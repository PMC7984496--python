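"""DVHs, plan-quality indices, clinical constraint checking and the
skin-dose overestimation statistic.

Index definitions (PD = prescribed dose per fraction):

* CI  (coverage index)     = PTV_PD / V_PTV — fraction of the PTV receiving PD
* COIN (conformal index)   = (PTV_PD / V_PTV) * (PTV_PD / V_PD)
* DHI (homogeneity index)  = (V_PD − V_1.5PD) / V_PD
* DNR (non-uniformity)     = V_1.5PD / V_PD          (DHI + DNR = 1)
* OI  (overdose index)     = V200 / V_PTV
* D95                      = dose to 95% of the PTV, as % of PD

V_PD and V_1.5PD are whole-body volumes; PTV_PD is the PTV/isodose
intersection; V100/V150/V200 are PTV volumes receiving 100/150/200% of PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import DoseGrid


# ---------------------------------------------------------------------------
# DVH


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH: volume (cc) receiving at least each edge dose (cGy)."""

    structure: str
    dose_edges_cgy: np.ndarray
    volume_cc: np.ndarray  # nonincreasing; volume_cc[0] = structure volume

    def __post_init__(self):
        if np.any(np.diff(self.volume_cc) > 1e-12):
            raise ValueError("cumulative DVH must be nonincreasing")

    @property
    def total_volume_cc(self) -> float:
        return float(self.volume_cc[0])


def cumulative_dvh(dose_values_cgy, voxel_volume_cc: float,
                   bin_width_cgy: float = 1.0,
                   structure: str = "structure") -> DVHCurve:
    """Exact voxel-counting cumulative DVH.

    ``volume_cc[k]`` counts voxels with dose >= ``dose_edges_cgy[k]`` times
    the voxel volume; no interpolation enters the curve itself.
    """
    d = np.asarray(dose_values_cgy, float).ravel()
    if d.size == 0:
        raise ValueError("empty structure: no voxels to histogram")
    if bin_width_cgy <= 0:
        raise ValueError("bin width must be > 0")
    n_bins = int(np.ceil((d.max() + bin_width_cgy) / bin_width_cgy)) + 1
    edges = np.arange(n_bins) * bin_width_cgy
    # voxels with dose >= edge: total minus count of dose < edge
    counts = d.size - np.searchsorted(np.sort(d), edges, side="left")
    return DVHCurve(structure, edges, counts * voxel_volume_cc)


def dvh_from_grid(dose: DoseGrid, mask, bin_width_cgy: float = 1.0,
                  structure: str = "structure") -> DVHCurve:
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    return cumulative_dvh(dose.values_cgy[mask], dose.grid.voxel_volume_cc,
                          bin_width_cgy, structure)


def volume_at_dose(dvh: DVHCurve, dose_cgy: float) -> float:
    """V(d): volume receiving at least ``dose_cgy``, linear inside the bin."""
    e, v = dvh.dose_edges_cgy, dvh.volume_cc
    if dose_cgy <= e[0]:
        return float(v[0])
    if dose_cgy >= e[-1]:
        return float(v[-1])
    return float(np.interp(dose_cgy, e, v))


def dose_at_volume(dvh: DVHCurve, volume_cc: float) -> float:
    """D(v): minimum dose received by the hottest ``volume_cc``.

    The highest dose edge whose cumulative volume still reaches
    ``volume_cc``, linearly interpolated inside the boundary bin.
    """
    if volume_cc > dvh.total_volume_cc + 1e-12:
        raise ValueError(
            f"requested volume {volume_cc} cc exceeds structure volume "
            f"{dvh.total_volume_cc} cc"
        )
    e, v = dvh.dose_edges_cgy, dvh.volume_cc
    above = np.nonzero(v >= volume_cc - 1e-12)[0]
    i = above[-1]
    if i == v.size - 1 or v[i] <= volume_cc + 1e-12:
        return float(e[i])
    frac = (v[i] - volume_cc) / (v[i] - v[i + 1])
    return float(e[i] + frac * (e[i + 1] - e[i]))


def dose_at_volume_fraction(dvh: DVHCurve, fraction: float) -> float:
    """D_x%: dose to the hottest ``fraction`` of the structure (e.g. D50%)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return dose_at_volume(dvh, fraction * dvh.total_volume_cc)


# ---------------------------------------------------------------------------
# Indices


def coverage_index(ptv_pd_cc: float, v_ptv_cc: float) -> float:
    if v_ptv_cc <= 0:
        raise ValueError("PTV volume must be > 0")
    return ptv_pd_cc / v_ptv_cc


def conformal_index(ptv_pd_cc: float, v_ptv_cc: float, v_pd_cc: float) -> float:
    if ptv_pd_cc > min(v_ptv_cc, v_pd_cc) + 1e-9:
        raise ValueError("PTV_PD cannot exceed V_PTV or V_PD")
    if v_ptv_cc <= 0 or v_pd_cc <= 0:
        raise ValueError("volumes must be > 0")
    return (ptv_pd_cc / v_ptv_cc) * (ptv_pd_cc / v_pd_cc)


def homogeneity_indices(v_pd_cc: float, v_15pd_cc: float):
    """(DHI, DNR); DHI + DNR = 1 exactly."""
    if v_pd_cc <= 0:
        raise ValueError("V_PD must be > 0")
    if not 0 <= v_15pd_cc <= v_pd_cc + 1e-9:
        raise ValueError("V_1.5PD must lie in [0, V_PD]")
    dnr = v_15pd_cc / v_pd_cc
    return 1.0 - dnr, dnr


def overdose_index(v200_cc: float, v_ptv_cc: float) -> float:
    if v_ptv_cc <= 0:
        raise ValueError("PTV volume must be > 0")
    return v200_cc / v_ptv_cc


def overestimation_ratio(d_tps_cgy: float, d_measured_cgy: float) -> float:
    """Percent by which the TPS overestimates: 100*(TPS − measured)/TPS."""
    if d_tps_cgy <= 0:
        raise ValueError("TPS dose must be > 0")
    return 100.0 * (d_tps_cgy - d_measured_cgy) / d_tps_cgy


def total_dose(dose_per_fraction_cgy: float, n_fractions: int) -> float:
    return dose_per_fraction_cgy * n_fractions


# ---------------------------------------------------------------------------
# Whole-plan metric extraction


def compute_plan_metrics(dose: DoseGrid, structures, pd_cgy: float,
                         oar_dose_overrides: dict | None = None) -> dict:
    """All target and OAR quantities for one plan.

    ``oar_dose_overrides`` optionally maps a structure name
    (``skin_region``, ``ipsilateral_lung``, ``heart``, ``involved_ribs``) to
    a ``(dose_values_cgy, voxel_volume_cc)`` pair evaluated on a dedicated
    grid — finer for the thin 3 mm skin region and rib layer, extending
    beyond the body grid for lung and heart.  Structures without an
    override are evaluated on the main grid where present.
    """
    ov = oar_dose_overrides or {}

    def _vals(name):
        if name in ov:
            v, vvo = ov[name]
            return np.asarray(v, float).ravel(), vvo
        if name in structures and np.any(structures[name]):
            return dose.values_cgy[structures[name]], dose.grid.voxel_volume_cc
        return None, None

    g = dose.grid
    vv = g.voxel_volume_cc
    d = dose.values_cgy

    ptv = structures["ptv"]
    dp = d[ptv]
    v_ptv = dp.size * vv
    m = {
        "pd_cgy": pd_cgy,
        "v_pd_cc": float(np.count_nonzero(d >= pd_cgy)) * vv,
        "v_15pd_cc": float(np.count_nonzero(d >= 1.5 * pd_cgy)) * vv,
        "v_ptv_cc": v_ptv,
        "ptv_pd_cc": float(np.count_nonzero(dp >= pd_cgy)) * vv,
        "v100_cc": float(np.count_nonzero(dp >= pd_cgy)) * vv,
        "v150_cc": float(np.count_nonzero(dp >= 1.5 * pd_cgy)) * vv,
        "v200_cc": float(np.count_nonzero(dp >= 2.0 * pd_cgy)) * vv,
    }
    m["ci"] = coverage_index(m["ptv_pd_cc"], m["v_ptv_cc"])
    m["coin"] = conformal_index(m["ptv_pd_cc"], m["v_ptv_cc"], m["v_pd_cc"])
    m["dhi"], m["dnr"] = homogeneity_indices(m["v_pd_cc"], m["v_15pd_cc"])
    m["oi"] = overdose_index(m["v200_cc"], m["v_ptv_cc"])
    ptv_dvh = cumulative_dvh(dp, vv, structure="ptv")
    m["d95_pct"] = 100.0 * dose_at_volume_fraction(ptv_dvh, 0.95) / pd_cgy

    lung, lvv = _vals("ipsilateral_lung")
    if lung is not None:
        m["lung_mean_cgy"] = float(lung.mean())
        m["lung_d01cc_cgy"] = dose_at_volume(
            cumulative_dvh(lung, lvv, structure="lung"), 0.1)
    heart, hvv = _vals("heart")
    if heart is not None:
        m["heart_mean_cgy"] = float(heart.mean())
        m["heart_d01cc_cgy"] = dose_at_volume(
            cumulative_dvh(heart, hvv, structure="heart"), 0.1)
    if "ipsilateral_breast" in structures:
        nt = structures["ipsilateral_breast"] & ~ptv
        dn = d[nt]
        m["breast_v90_pct"] = 100.0 * float(np.count_nonzero(dn >= 0.9 * pd_cgy)) / dn.size
        breast_dvh = cumulative_dvh(dn, vv, structure="nontarget_breast")
        m["breast_d90pct_cgy"] = dose_at_volume_fraction(breast_dvh, 0.90)
    rib, rvv = _vals("involved_ribs")
    if rib is not None and rib.size:
        rib_dvh = cumulative_dvh(rib, rvv, structure="involved_ribs")
        m["rib_v80_cc"] = float(np.count_nonzero(rib >= 0.8 * pd_cgy)) * rvv
        m["rib_v90_cc"] = float(np.count_nonzero(rib >= 0.9 * pd_cgy)) * rvv
        m["rib_d1cc_cgy"] = dose_at_volume(rib_dvh, min(1.0, rib.size * rvv))
        m["rib_d01cc_cgy"] = dose_at_volume(rib_dvh, 0.1)

    sd, svv = _vals("skin_region")
    if sd is not None:
        skin_dvh = cumulative_dvh(sd, svv, structure="skin_region")
        m["skin_v100_cc"] = float(np.count_nonzero(sd >= pd_cgy)) * svv
        m["skin_v90_cc"] = float(np.count_nonzero(sd >= 0.9 * pd_cgy)) * svv
        m["skin_d1cc_cgy"] = dose_at_volume(skin_dvh, min(1.0, sd.size * svv))
        m["skin_d02cc_cgy"] = dose_at_volume(skin_dvh, 0.2)
        m["skin_d50pct_cgy"] = dose_at_volume_fraction(skin_dvh, 0.50)
    return m


# ---------------------------------------------------------------------------
# Constraints


#: (report label, metric key, limit, kind)
#: kind 'dose' compares a cGy/fraction metric against limit*PD;
#: kind 'pct'  compares a percent-of-volume metric against the limit in %.
CONSTRAINT_DEFINITIONS = (
    ("skin D0.2cc < 100% PD", "skin_d02cc_cgy", 1.00, "dose"),
    ("skin D1cc < 90% PD", "skin_d1cc_cgy", 0.90, "dose"),
    ("rib D0.1cc < 90% PD", "rib_d01cc_cgy", 0.90, "dose"),
    ("rib D1cc < 80% PD", "rib_d1cc_cgy", 0.80, "dose"),
    ("breast V90%PD < 10% of volume", "breast_v90_pct", 10.0, "pct"),
    ("heart mean < 8% PD", "heart_mean_cgy", 0.08, "dose"),
    ("heart D0.1cc < 50% PD", "heart_d01cc_cgy", 0.50, "dose"),
    ("lung mean < 8% PD", "lung_mean_cgy", 0.08, "dose"),
    ("lung D0.1cc < 60% PD", "lung_d01cc_cgy", 0.60, "dose"),
)


@dataclass
class ConstraintReport:
    rows: list
    pd_cgy: float

    @property
    def all_pass(self) -> bool:
        return all(r["passed"] for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def constraint_thresholds(pd_cgy: float) -> dict:
    """Threshold in cGy/fraction for every dose limit, given the prescription."""
    return {label: frac * pd_cgy for label, _, frac, kind in CONSTRAINT_DEFINITIONS
            if kind == "dose"}


def check_constraints(metrics: dict, pd_cgy: float,
                      require_all: bool = False) -> ConstraintReport:
    """Evaluate every clinical limit; thresholds are the stated % of PD.

    With ``require_all`` a missing metric raises; otherwise missing OARs
    (e.g. a rib region the implant never overlies) are reported as absent.
    """
    rows = []
    for label, key, frac, kind in CONSTRAINT_DEFINITIONS:
        threshold = frac * pd_cgy if kind == "dose" else frac
        if key not in metrics:
            if require_all:
                raise KeyError(f"metric {key!r} required by constraint {label!r}")
            rows.append(dict(constraint=label, metric=key, value=np.nan,
                             threshold=threshold, passed=True, evaluated=False))
            continue
        value = metrics[key]
        rows.append(dict(constraint=label, metric=key, value=float(value),
                         threshold=threshold, passed=bool(value < threshold),
                         evaluated=True))
    return ConstraintReport(rows=rows, pd_cgy=pd_cgy)


# ---------------------------------------------------------------------------
# Cohort summaries (study-shaped tables)


def summarize_cohort(per_case: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mean/median/max/min/SD rows for each metric column, the shape used by
    the study's target and OAR tables."""
    cols = columns if columns is not None else [
        c for c in per_case.columns if np.issubdtype(per_case[c].dtype, np.number)
    ]
    out = {}
    for c in cols:
        v = per_case[c].to_numpy(float)
        out[c] = dict(mean=v.mean(), median=float(np.median(v)),
                      max=v.max(), min=v.min(), sd=v.std(ddof=1))
    return pd.DataFrame(out).T[["mean", "median", "max", "min", "sd"]]


def dhi_stats_from_dnr(dnr_mean: float, dnr_median: float, dnr_min: float):
    """DHI summary statistics implied by DNR statistics through DHI = 1 − DNR
    (mean and median commute with the affine map; max DHI pairs with min DNR)."""
    return 1.0 - dnr_mean, 1.0 - dnr_median, 1.0 - dnr_min
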