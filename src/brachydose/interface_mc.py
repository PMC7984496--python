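"""Photon Monte Carlo for the tissue-air interface backscatter deficit.

The TG-43 formalism assumes full-scatter water around the source; near the
skin the missing backscatter lowers the true dose.  This module transports
photons analogically in water (exponential free paths, free-electron
Klein-Nishina Compton scattering, photoelectric = local absorption, kerma
approximation — no electron transport, no Rayleigh) and scores collision
kerma at point tallies with a next-event (expected-value) estimator at the
emission vertex and at every Compton vertex.

Both geometries come from one correlated run: the half-space result is
obtained by exact history tagging — a history stops contributing to the
half-space tally at its first crossing of the interface plane z = 0
(air side modeled as vacuum), which reproduces the half-space analog
ensemble exactly while sharing every random number with the full-water
estimate.  The observable is the per-tally deficit
100 * (D_full − D_half) / D_full.

Doses are in arbitrary but internally consistent units
(MeV * cm^-2 * cm^2/g per emitted photon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import xsections as xs
from .implant import PhantomSetup, build_phantom_plan

FOUR_PI = 4.0 * np.pi


@dataclass(frozen=True)
class MCConfig:
    n_histories: int = 200_000
    seed: int = 0
    energy_mev: float = 0.38
    cutoff_mev: float = 0.01
    geometry: str = "half_space"  # or "full_water"
    scatter: bool = True
    batch_size: int = 100_000
    n_se_batches: int = 16
    min_tally_distance_cm: float = 0.2

    def __post_init__(self):
        if self.n_histories < 1:
            raise ValueError("need at least one history")
        if self.cutoff_mev <= 0:
            raise ValueError("cutoff energy must be > 0")
        if self.geometry not in ("half_space", "full_water"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class MCResult:
    """Per-tally full-scatter and half-space dose estimates and the deficit."""

    labels: list
    dose_full: np.ndarray
    se_full: np.ndarray
    dose_half: np.ndarray
    se_half: np.ndarray
    deficit_pct: np.ndarray
    deficit_se_pct: np.ndarray
    n_histories: int
    seed: int
    meta: dict = field(default_factory=dict)


def _rotate(directions: np.ndarray, cos_t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(cos_t), azimuth phi."""
    u = directions
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    # orthonormal frame (a, b, u); pick helper axis away from u
    helper = np.zeros_like(u)
    small = np.abs(u[:, 2]) < 0.9
    helper[small, 2] = 1.0
    helper[~small, 0] = 1.0
    a = np.cross(helper, u)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = np.cross(u, a)
    return (
        u * cos_t[:, None]
        + (a * np.cos(phi)[:, None] + b * np.sin(phi)[:, None]) * sin_t[:, None]
    )


def _sample_compton(rng, energy_mev: np.ndarray) -> np.ndarray:
    """Sample x = E'/E from the Klein-Nishina spectrum by rejection
    (f(x) = x + 1/x − sin^2(theta) under envelope 1/x_min + 1)."""
    a = energy_mev / xs.ELECTRON_REST_MEV
    x_min = 1.0 / (1.0 + 2.0 * a)
    x = np.empty_like(energy_mev)
    todo = np.ones(energy_mev.shape[0], bool)
    bound = 1.0 / x_min + 1.0
    while np.any(todo):
        n = int(todo.sum())
        xt = x_min[todo] + (1.0 - x_min[todo]) * rng.random(n)
        cos_t = 1.0 + (1.0 - 1.0 / xt) / a[todo]
        sin2 = 1.0 - cos_t**2
        f = xt + 1.0 / xt - sin2
        accept = rng.random(n) * bound[todo] < f
        idx = np.nonzero(todo)[0]
        x[idx[accept]] = xt[accept]
        todo[idx[accept]] = False
    return x


def _point_kerma(vertex_cm: np.ndarray, tallies_cm: np.ndarray,
                 energy_det: np.ndarray, pdf_omega: np.ndarray,
                 d_min_cm: float) -> np.ndarray:
    """(n, T) next-event contributions given per-tally detector energies
    (n, T) and angular pdfs (n, T)."""
    diff = tallies_cm[None, :, :] - vertex_cm[:, None, :]
    d = np.maximum(np.linalg.norm(diff, axis=2), d_min_cm)
    mu_d = xs.mu_water(energy_det)
    return (
        pdf_omega * np.exp(-mu_d * d) / d**2 * energy_det * xs.muen_water(energy_det)
    )


def transport_batch(rng, source_points_mm: np.ndarray, tally_points_mm: np.ndarray,
                    config: MCConfig, n: int):
    """Transport ``n`` histories; return per-history tallies and the energy
    ledger.

    Returns a dict with per-history arrays: ``full`` and ``half`` (n, T)
    tally contributions; ``emitted``, ``deposited_full``, ``deposited_half``,
    ``below_cutoff_full``, ``below_cutoff_half``, ``escaped_half`` (n,).
    """
    src = np.atleast_2d(np.asarray(source_points_mm, float)) / 10.0  # cm
    tal = np.atleast_2d(np.asarray(tally_points_mm, float)) / 10.0
    T = tal.shape[0]
    E0 = config.energy_mev
    d_min = config.min_tally_distance_cm

    pick = rng.integers(0, src.shape[0], size=n)
    pos = src[pick].copy()
    # isotropic emission
    cos_t = 1.0 - 2.0 * rng.random(n)
    phi = 2.0 * np.pi * rng.random(n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    u = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    E = np.full(n, E0)

    full = np.zeros((n, T))
    half = np.zeros((n, T))
    ledger = {
        "emitted": np.full(n, E0),
        "deposited_full": np.zeros(n),
        "deposited_half": np.zeros(n),
        "below_cutoff_full": np.zeros(n),
        "below_cutoff_half": np.zeros(n),
        "escaped_half": np.zeros(n),
    }

    # emission next-event term (pdf = 1/4pi), counts for both geometries
    contrib = _point_kerma(pos, tal, np.full((n, T), E0),
                           np.full((n, T), 1.0 / FOUR_PI), d_min)
    full += contrib
    half += contrib

    alive = np.ones(n, bool)
    half_alive = np.ones(n, bool)
    has_interface = config.geometry == "half_space"
    while np.any(alive):
        ia = np.nonzero(alive)[0]
        mu = xs.mu_water(E[ia])
        step = -np.log(rng.random(ia.size)) / mu
        new_pos = pos[ia] + step[:, None] * u[ia]

        if has_interface:
            crossing = half_alive[ia] & (new_pos[:, 2] < 0.0)
            ledger["escaped_half"][ia[crossing]] += E[ia[crossing]]
            half_alive[ia[crossing]] = False
        pos[ia] = new_pos

        # interaction type
        pe = rng.random(ia.size) < xs.photoelectric_fraction(E[ia])
        if not config.scatter:
            pe[:] = True
        i_pe = ia[pe]
        ledger["deposited_full"][i_pe] += E[i_pe]
        hh = half_alive[i_pe]
        ledger["deposited_half"][i_pe[hh]] += E[i_pe[hh]]
        alive[i_pe] = False

        i_c = ia[~pe]
        if i_c.size:
            # score BEFORE sampling the outgoing state (incoming E, u)
            diff = tal[None, :, :] - pos[i_c][:, None, :]
            d = np.linalg.norm(diff, axis=2)
            cos_det = np.einsum("nj,ntj->nt", u[i_c], diff) / np.maximum(d, 1e-12)
            a = E[i_c] / xs.ELECTRON_REST_MEV
            x_det = 1.0 / (1.0 + a[:, None] * (1.0 - cos_det))
            e_det = x_det * E[i_c][:, None]
            pdf = (
                xs.klein_nishina_dcs(E[i_c][:, None], cos_det)
                / xs.klein_nishina_total(E[i_c])[:, None]
            )
            c = _point_kerma(pos[i_c], tal, e_det, pdf, d_min)
            full[i_c] += c
            hmask = half_alive[i_c]
            half[i_c[hmask]] += c[hmask]

            # analog outgoing state
            xr = _sample_compton(rng, E[i_c])
            cos_sc = 1.0 + (1.0 - 1.0 / xr) / a
            phi_sc = 2.0 * np.pi * rng.random(i_c.size)
            e_new = xr * E[i_c]
            transfer = E[i_c] - e_new
            ledger["deposited_full"][i_c] += transfer
            ledger["deposited_half"][i_c[hmask]] += transfer[hmask]
            u[i_c] = _rotate(u[i_c], cos_sc, phi_sc)
            E[i_c] = e_new

            below = e_new < config.cutoff_mev
            ib = i_c[below]
            ledger["below_cutoff_full"][ib] += E[ib]
            bb = half_alive[ib]
            ledger["below_cutoff_half"][ib[bb]] += E[ib[bb]]
            alive[ib] = False

    return {"full": full, "half": half, **ledger}


def transport_photon(rng, source_point_mm, tally_points_mm, config: MCConfig):
    """Single-history transport (n = 1 batch); returns the same ledger."""
    return transport_batch(rng, np.atleast_2d(source_point_mm),
                           tally_points_mm, config, 1)


def simulate(source_points_mm, tally_points_mm, config: MCConfig,
             labels=None) -> MCResult:
    """Run ``config.n_histories`` histories and estimate full-water and
    half-space tally doses, their standard errors, and the deficit."""
    rng = np.random.default_rng(config.seed)
    tal = np.atleast_2d(np.asarray(tally_points_mm, float))
    T = tal.shape[0]
    n_total = config.n_histories
    nb = min(config.n_se_batches, n_total)
    per = [n_total // nb + (1 if i < n_total % nb else 0) for i in range(nb)]

    sum_f = np.zeros(T)
    sumsq_f = np.zeros(T)
    sum_h = np.zeros(T)
    sumsq_h = np.zeros(T)
    batch_f = np.zeros((nb, T))
    batch_h = np.zeros((nb, T))
    for b, nb_hist in enumerate(per):
        done = 0
        while done < nb_hist:
            m = min(config.batch_size, nb_hist - done)
            out = transport_batch(rng, source_points_mm, tal, config, m)
            sum_f += out["full"].sum(axis=0)
            sumsq_f += (out["full"] ** 2).sum(axis=0)
            sum_h += out["half"].sum(axis=0)
            sumsq_h += (out["half"] ** 2).sum(axis=0)
            batch_f[b] += out["full"].sum(axis=0)
            batch_h[b] += out["half"].sum(axis=0)
            done += m

    n = float(n_total)
    mean_f = sum_f / n
    mean_h = sum_h / n
    se_f = np.sqrt(np.maximum(sumsq_f / n - mean_f**2, 0.0) / n)
    se_h = np.sqrt(np.maximum(sumsq_h / n - mean_h**2, 0.0) / n)

    with np.errstate(divide="ignore", invalid="ignore"):
        deficit = 100.0 * (mean_f - mean_h) / mean_f
        bd = 100.0 * (batch_f - batch_h) / batch_f
    deficit_se = bd.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 else np.full(T, np.inf)

    return MCResult(
        labels=list(labels) if labels is not None else [str(i) for i in range(T)],
        dose_full=mean_f, se_full=se_f,
        dose_half=mean_h, se_half=se_h,
        deficit_pct=deficit, deficit_se_pct=deficit_se,
        n_histories=n_total, seed=config.seed,
        meta={"energy_mev": config.energy_mev, "cutoff_mev": config.cutoff_mev},
    )


def result_for_geometry(res: MCResult, geometry: str):
    """(dose, se) arrays of one geometry from a correlated result."""
    if geometry == "full_water":
        return res.dose_full, res.se_full
    if geometry == "half_space":
        return res.dose_half, res.se_half
    raise ValueError(f"unknown geometry {geometry!r}")


def _phantom_sources_mm(depth_mm: float, separation_cm: float = 2.0,
                        length_mm: float = 100.0) -> np.ndarray:
    setup = PhantomSetup(variant="surface_points", catheter_depth_mm=depth_mm,
                         catheter_separation_cm=separation_cm,
                         catheter_length_mm=length_mm)
    plan = build_phantom_plan(setup)
    pos, _ = plan.dwell_geometry
    return pos


def surface_deficit(depths_mm=(5.0, 10.0, 15.0, 20.0),
                    config: MCConfig = MCConfig(),
                    separation_cm: float = 2.0) -> MCResult:
    """Backscatter deficit at surface points directly above a catheter of
    the two-catheter phantom, one tally per catheter depth.

    Histories are split evenly over depths; each depth gets its own
    correlated full/half pair (the source geometry changes with depth).
    """
    depths = list(depths_mm)
    n_per = max(1, config.n_histories // len(depths))
    results = []
    for i, depth in enumerate(depths):
        src = _phantom_sources_mm(depth, separation_cm)
        tally = np.array([[-separation_cm * 10.0 / 2.0, 0.0, 0.0]])
        sub = MCConfig(n_histories=n_per, seed=config.seed + i,
                       energy_mev=config.energy_mev, cutoff_mev=config.cutoff_mev,
                       geometry=config.geometry, scatter=config.scatter,
                       batch_size=config.batch_size,
                       n_se_batches=config.n_se_batches,
                       min_tally_distance_cm=config.min_tally_distance_cm)
        results.append(simulate(src, tally, sub, labels=[f"depth_{depth:g}mm"]))

    return MCResult(
        labels=[r.labels[0] for r in results],
        dose_full=np.concatenate([r.dose_full for r in results]),
        se_full=np.concatenate([r.se_full for r in results]),
        dose_half=np.concatenate([r.dose_half for r in results]),
        se_half=np.concatenate([r.se_half for r in results]),
        deficit_pct=np.concatenate([r.deficit_pct for r in results]),
        deficit_se_pct=np.concatenate([r.deficit_se_pct for r in results]),
        n_histories=n_per * len(depths), seed=config.seed,
        meta={"depths_mm": depths, "separation_cm": separation_cm},
    )


def perpendicular_film_profile(setup: PhantomSetup,
                               config: MCConfig = MCConfig(),
                               x_range_mm: float = 40.0,
                               x_step_mm: float = 5.0) -> MCResult:
    """Deficit profile along a surface strip perpendicular to the catheters
    (the film placed across the implant, catheters 2 cm deep).

    Tally points run along x on the skin at y = 0; the profile is symmetric
    about the midline between the two catheters.  The summary deficit is the
    profile mean, stored in ``meta['summary_deficit_pct']``.
    """
    if setup.variant != "perpendicular_film":
        raise ValueError("setup variant must be 'perpendicular_film'")
    plan = build_phantom_plan(setup)
    src, _ = plan.dwell_geometry
    xg = np.arange(-x_range_mm, x_range_mm + 1e-9, x_step_mm)
    tallies = np.column_stack([xg, np.zeros_like(xg), np.zeros_like(xg)])
    res = simulate(src, tallies, config, labels=[f"x_{x:+.0f}mm" for x in xg])
    res.meta.update(
        x_mm=xg.tolist(),
        summary_deficit_pct=float(np.mean(res.deficit_pct)),
        summary_deficit_se_pct=float(
            np.linalg.norm(res.deficit_se_pct) / len(xg)
        ),
    )
    return res
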