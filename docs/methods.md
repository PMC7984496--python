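# Methods

This note documents the models, numerical choices and known limits of the
package. It describes what the code computes; every empirical number shown
by the tests, the analysis scripts or `scripts/acceptance.py` is produced
by running that code.

## TG-43 dose model (`sources`, `engine`)

Dose rate around a dwell follows the standard factorization
`D = S_K Λ [G(r,θ)/G(r₀,θ₀)] g_L(r) F(r,θ)` in an infinite water medium.

* Geometry factor: point mode `1/r²`; line mode `β/(L r sinθ)` with `β`
  computed as the difference of the polar angles of the two end vectors
  (numerically stable for short lines, unlike the arccos of the dot
  product). Within `sinθ < 1e-7` of the long axis the analytic limit
  `1/(r² − L²/4)` is used; the two expressions agree to O(θ²), so the
  branch choice is irrelevant at 1e-14 relative.
* `g_L(r)`: log-linear interpolation in r; constant below the first table
  radius, last-segment ln-slope extension above the last. `F(r,θ)`:
  bilinear, clamped to the table bounds. Tables are validated on
  construction (`g_L(1 cm) = 1`, `F(r, 90°) = 1`, positive, increasing
  axes).
* Units: cm inside the source model, mm in patient space, seconds for
  dwell times, cGy for dose; the conversion happens once at the module
  boundary.
* Two bundled sources: a **unit-test source** (point mode, `g ≡ 1`,
  `F ≡ 1`, Λ = 1.109 placeholder) used throughout the tests, and a
  **synthetic representative Ir-192 line source** (L = 3.6 mm) whose `g`
  and `F` tables have the familiar qualitative shape of published HDR
  Ir-192 data but are not any vendor's consensus dataset. Clinical tables
  load from CSV (`radial.csv`, `anisotropy.csv`, `source.json`).
* The dose engine superposes dwells exactly (no approximation); chunking
  is a memory tactic and the chunked path mirrors the per-point evaluation
  operation-for-operation, so results are independent of chunk size.
  Points closer than 1 mm to a dwell are evaluated at r = 1 mm and
  counted on the returned grid (`n_capped_voxels`); clinical planning
  systems are likewise not valid in the near field.

## Implant geometry (`implant`)

Catheters are straight inside tissue (the free-hand needles are rigid
steel); the polyline path type supports curvature for completeness.
Buttons are the skin projections of the path endpoints — the securing
points sit on the skin while the needle runs at depth, so the button/path
coincidence is enforced laterally. Dwells step 5 mm along arc length with
a 5 mm tip retraction by default (afterloader practice; configurable).
The free-hand generator tiles the cross-sectional footprint of the cavity
plus margin with one or two catheter planes at 1.5–2 cm pitch, the second
plane offset by half a spacing (triangular packing) and separated by
`(√3/2)·spacing`; every catheter stays ≥ 5 mm below the skin, or the
generator raises an infeasibility error naming the violated depth.

## Anatomy (`anatomy`)

Grids use the voxel-center convention with x lateral, y cranio-caudal
(2.5 mm, the CT slice direction) and z depth, skin plane at z = 0.
Margins (`expand_margin`) are Euclidean and isotropic via a distance
transform on voxel centers; with center-distance semantics the discrete
boundary sits up to half a voxel diagonal inside the continuous surface,
a ~3% volume deficit for a 3 cm sphere at 1×1×2.5 mm — the tests budget
for exactly that. The study-specific skin region is the quadrilateral on
the skin whose short sides are the outermost button edges and whose long
sides parallel the outermost catheters' projections displaced 1 cm
outward, extruded 3 mm deep; one catheter degenerates to a 2 cm strip.
Involved ribs are the rib layer under that footprint.

## Optimization (`optimize`)

No clinical inverse-planning algorithm is replicated; the package uses the
simplest auditable stand-in producing plans of the study's shape:

1. **Geometric weighting** — each dwell's relative time inversely
   proportional to the dose rate it receives from all other dwells
   (classical volume-implant rule; boosts peripheral dwells).
2. Optional **nonnegative least squares** of the dose at quasi-uniform
   PTV-boundary points (seeded sampling, default 200 points) against the
   coverage dose.
3. **Coverage normalization** — the smallest global time scale k with
   `V_{0.95·PD}(PTV) ≥ 95%`, found by bisection to 0.1% with coverage
   monotonicity asserted at every step.
4. **OAR cap** — every dose-type clinical limit (skin D0.2cc/D1cc, rib
   D0.1cc/D1cc, heart and lung mean/D0.1cc) is linear in the global
   scale, and the nontarget-breast V90% limit converts to a bound through
   its 90th dose percentile; the coverage scale is capped at the largest
   value satisfying all of them (times 0.995 for DVH re-binning margin).
   This emulates the clinical trade-off in which organ limits are hard
   and target coverage yields — the resulting plans sit below the 95%
   coverage goal exactly as clinically reported plans tend to.

## Metrics (`metrics`)

Cumulative DVHs are exact voxel counts per 1 cGy bin; Dx/Vx interpolate
linearly inside the boundary bin only. `V_PD` and `V_1.5PD` are
whole-grid ("body") volumes; `PTV_PD` is the PTV∩isodose volume;
V100/150/200 are PTV volumes. DHI + DNR = 1 holds identically by
construction, and COIN ≤ CI because `PTV_PD ≤ V_PD`. The thin skin
region (3 mm) and rib layer (5 mm) are evaluated on dedicated finer point
grids, and lung/heart on 5 mm grids extending 10 cm behind the chest
slab, mirroring how a planning system scores OARs over their full
contours rather than on a cropped dose grid. The constraint checker
derives every threshold from the prescription (e.g. skin D1cc < 90% of
340 = 306 cGy/fraction); the nontarget-breast limit is the volume
fraction receiving 90% of PD staying under 10%.

## Interface Monte Carlo (`interface_mc`, `xsections`)

Analog photon transport in water at 0.38 MeV (the Ir-192 mean energy):
exponential free paths from a compact table of standard published
attenuation/energy-absorption coefficients (log-log interpolated),
free-electron Klein–Nishina Compton sampling (rejection on the `E'/E`
spectrum), photoelectric events as local absorption, kerma approximation
(no electron transport), Rayleigh ignored — all second-order for a
deficit *ratio* at this energy. Point tallies use a next-event
(expected-value) collision-kerma estimator at the emission vertex and at
every Compton vertex; a 2 mm minimum tally distance bounds the 1/d²
estimator variance (the bias is sub-percent and almost cancels in the
ratio). Energy bookkeeping (deposited + below-cutoff + escaped = emitted)
is exact per history.

The half-space geometry is realized by exact history tagging inside one
full-water run: a history stops contributing to the half-space tally at
its first crossing of the skin plane (air is vacuum — no backscatter).
This reproduces the half-space analog ensemble exactly while sharing
every random number with the full-water estimate, so the deficit
`100·(D_full − D_half)/D_full` is estimated with strongly correlated
numerators. Standard errors come from per-history moments (doses) and
16 batch replicates (deficit ratio). With `geometry="full_water"` the
tagging is disabled and the deficit is identically zero — the machinery
control. Note that at 10–15 cm from the interface a genuine residual
deficit of ~0.2% remains and the correlated estimator resolves it; the
far-interface check therefore asserts negligibility (< 0.5%), not a
statistical zero.

The measured film values of the source study (1.7/9.4/13.4/19.1/20.1%)
are physical measurements including film response and setup effects; the
MC asserts only sign, depth monotonicity and order of magnitude (deficit
at 15–20 mm depth within 5–35%), never those numbers.

## Synthetic cohort (`cohort`)

The generator emulates the study conditions — 17 patients, 340 cGy × 10,
two-plane free-hand implants, PTV volumes spanning roughly 32–125 cc —
with a minimal geometry exposing every reported quantity:

* Breast: half-ellipsoid flattened against the skin plane (supine
  posture), lateral radius lognormal ln(60 mm)±0.12 clipped to
  [45, 80] mm, thickness lognormal ln(32 mm)±0.13 clipped to [26, 42] mm
  — the thin-breast anatomy for which one or two implant planes suffice.
  Chest slab behind the breast with a 5 mm rib layer; lung and heart as
  deep layers (heart medial and 10 mm deeper).
* Cavity volume lognormal ln(3 cc)±0.7 clipped to [0.8, 8] cc, placed at
  a depth drawn uniformly over the feasible band (≥ 7 mm cover above, ≥
  5 mm tissue below); infeasible draws are rejected and counted.
* CTV = cavity + 2 cm and PTV = CTV + 0.5 cm, cropped to breast tissue
  and to ≥ 5 mm below the skin (standard interstitial-APBI practice);
  the cropped fraction is recorded. These choices were fixed once, at
  design time, to land the PTV span and make the clinical limits
  satisfiable, and not revisited.
* Implant planes straddle the cavity with a 7 mm depth floor (clinicians
  keep margin beyond the 5 mm hard rule); catheters tile the PTV
  footprint.
* Film emulation: measured = TPS skin D50% × (1 − deficit(depth)) ×
  lognormal noise (σ = 0.03, mean 1), with the deficit logistic in the
  shallowest catheter depth (asymptote 0.35, midpoint 7.5 mm, scale
  2.5 mm) — calibrated once so the deficit spans ~0.15–0.33 over the
  generated 7–15 mm depth range, matching the band the film study
  reported. Asymptote recovery fits only the amplitude with the shape
  known; the narrow depth range does not identify all three logistic
  parameters from 17 points, and the recovery claim is scoped
  accordingly. Because the overestimation ratio is algebraically
  independent of the absolute TPS dose, recovery replicates draw depths
  and ratios through the generator without re-running the dose engine.

**What passing tests do and do not show.** The cohort exercises every
pipeline stage with realistic magnitudes, but it is not patient data: the
anatomy is convex and layered, catheters are perfectly straight and
parallel, the film "measurement" is the generator's own deficit model
plus noise, and CT artifacts, contouring variability, seroma, and needle
deflection are absent. Agreement of indices computed here with their
defining identities says the metric code is right; it does not validate
the generator against clinical distributions. The cohort's coverage
indices run below the clinical report's (median CI ≈ 0.5–0.8 vs 0.94)
because the hard OAR cap meets every dose limit on a geometry whose PTV
always abuts the 5 mm skin line; real cavities vary in depth and real
optimizers shape dose locally rather than by a global scale.

## Problem sizes

Default scales chosen for desk-scale reproducibility: cohort dose grids
at 2.5 mm isotropic with per-OAR evaluation grids as above; a 17-patient
planned cohort in ~1 minute; Monte Carlo defaults of 2×10⁵ histories
(CLI) and 4×10⁵ (acceptance script) per run, giving deficit standard
errors of a few tenths of a percent; 20-seed geometry sweeps and
100-replicate recovery runs complete in seconds.
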