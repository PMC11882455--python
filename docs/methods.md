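# Methods

This note records the models, estimators and numerical choices behind
`mycowave`, and what the synthetic-data tests do and do not establish
about real imaging data.

## The BARE wave model (`barewave`)

Two coupled fields on a 1-D domain (Cartesian or radial): growing-tip
density *n* (mm⁻²) and filament density *ρ* (μm mm⁻²),

    ∂n/∂t = α n − β n ρ + ∇·J,    J = D_n ∇n − v n r̂
    ∂ρ/∂t = v n

Parameters, with defaults and units:

| symbol | meaning | default | unit |
|---|---|---|---|
| α | branching rate per tip | 0.04 | h⁻¹ |
| β | annihilation coefficient per tip per filament density | 23 | μm h⁻¹ |
| v | apical (tip advection) speed | 280 | μm h⁻¹ |
| D_n | tip diffusivity | 25 | μm² h⁻¹ |
| Δr, Δt | grid spacing / time step | 5 μm / 0.9×CFL | |

β multiplies ρ expressed per-micrometre (ρ[μm mm⁻²]·10⁻⁶ μm⁻¹), so βρ is a
rate: at ρ_sat ≈ 1,000 μm mm⁻² the per-tip annihilation rate βρ ≈ 2%/h.

Properties used as oracles:

- **Pulled front.** The leading edge is linear, so the front speed is
  c = v + 2√(αD_eff), with D_eff = D_n plus the upwind scheme's numerical
  diffusivity vΔr(1−ν)/2 (ν the CFL number). With the defaults the excess
  over v is ~1.5%. D_n is chosen so the *physical* excess 2√(αD_n) stays
  below 2% of v.
- **Wake balance.** In the wave frame, integrating the n-equation across
  the front and substituting n = −(c/v)ρ′ gives αρ_sat = βρ_sat²/2, i.e.
  ρ_sat = 2α/β, independent of D. The integrator reproduces it to <0.5%.
  The wake *approaches* this value only as the front matures, so
  `measure_wave` averages the plateau just behind the final front
  (0.85–0.97 of the front position), not the start-up wake near the
  origin.
- **Radial geometry.** The curvature term acts as an effective branching
  rate α − v/r; the radial front speed converges to the Cartesian value
  quickly, but the wake density converges only as 1/r and remains below
  the planar balance at centimetre scales.

Discretization: conservative first-order upwind advection, explicit
centred diffusion, forward Euler; monotone and positivity-preserving under
the validated CFL bound (tightened by a factor 2 in radial geometry for
the innermost cell). Negative values abort the run rather than being
clipped silently.

**Phosphorus extension.** ∂P/∂t = D_P∇²P − k_up·ρ·P with absorbed
phosphorus accumulated explicitly; written in flux form, total phosphorus
(medium + absorbed) is conserved to machine precision. The uptake law is
first-order in ρ and P — a declared modelling assumption (defaults
k_up = 0.015 mm h⁻¹, D_P = 3,600 μm² h⁻¹, P0 = 1). Carbon cost is γ times
total filament length; cost per phosphorus falls with wave speed because a
faster wave escapes its self-made depletion zone.

## The synthetic colony generator (`colonysim`)

Off-lattice 2-D agents: each growing tip advances v·dt along its heading
per step (Δt = 0.25 h, heading noise σ = 0.01 rad/step — runner hyphae are
nearly straight over centimetres), branches with probability α·dt
(daughters spawn at the parent apex, heading offset ±U(30°, 90°)), and on
crossing an existing filament fuses with probability p_fuse (tip removed,
three-way junction) or crosses (four-way junction). Tip speeds are drawn
once per tip from a truncated normal (mean 240, s.d. 25, range 200–280
μm/h); the front is pulled by the fastest, straightest tips rather than by
an imposed subpopulation. Initial hyphae fan out from barrier anchors over
15°–165°.

Calibration: the realized annihilation coefficient is
β_eff = p_fuse·v·⟨|sin θ|⟩ with ⟨|sin θ|⟩ ≈ 0.26 for the partially
radially aligned wake geometry, so p_fuse = 0.37 puts β_eff near the
measured 23 μm h⁻¹. Contact handling snaps the junction to the nearest
interior vertex of the host trail (within one 60–70 μm step), which keeps
the serialized decomposition exact without retroactive vertex insertion.

Two generator rules exist purely so that frame-based tracking can observe
every event it is tested against: newborn tips ignore contacts within
150 μm of their origin (they must displace ≥ 40 px = 130 μm to register as
growing tips), and branching stops one output frame before the end of the
run. Both are stated generator conditions, not post-hoc filters.

**Discreteness effect.** The ABM wake freezes a factor ~2 below the
mean-field 2α/β_eff: wake tips drift outward ballistically and their
small-number branching/annihilation dynamics go extinct before local
densification completes. This mirrors the gap between the measured
saturation density of real colonies (~10³ μm mm⁻²) and the mean-field
wake-balance estimate, and is asserted as such in the tests rather than
tuned away.

**Decorations.** BAS (branched absorbing structures) are added as bushes —
one attachment junction per bush, a primary branchlet with 1–3 laterals,
every edge < 400 μm, widths ~4 μm — scheduled frame-by-frame so
ρ_BAS = L_BAS/(L_RH+L_BAS) tracks its 30% target. Bushes (rather than
individual laterals) keep runner-hypha sub-edges long enough that the
length-based BAS classifier is not confounded by attachment junctions.
Spores are a Poisson process with intensity proportional to local filament
length (default 1.5·10⁻³ per mm·h, radius ~40 μm). Ground-truth per-edge
flow speeds follow |u| = k₁(BC−1)/N + k₂·d_tip (capped), the "excess
centrality" offset making tip edges carry exactly zero — defaults
k₁ = 10 μm/s, k₂ = 0.3 (μm/s)/mm, cap 12 μm/s.

## Data model (`netmodel`)

A colony is a set of *trails* (per-tip polylines with a lay-down time per
vertex) subdivided by junctions into edges. Junctions can form on a trail
long after it was laid (a later tip fuses with an old hypha), so the
serialized edge table stores the final junction-to-junction decomposition
plus each subdivision's formation time; `snapshot(t)` truncates polylines
at t and merges sub-edges across not-yet-formed junctions, reporting the
merged edge under its earliest constituent id. Element-id sets therefore
only grow with time, and an anastomosis junction inherits the annihilated
tip's node id — its tracked degree history reads 1 → 3, exactly the
signature the detectors key on (crossings revert to 1; four-way junctions
appear as new nodes). This mirrors what frame-by-frame skeleton extraction
plus tracking produces on images.

The CSV bundle (`nodes.csv`, `edges.csv`, `events.csv`, `spores.csv`,
`meta.json`) round-trips byte-identically; `edges.csv` carries the
polyline WKT plus per-vertex times and the subdivision time.

## Estimators (`waveprofile`, `events`)

- **Ring frame.** N equal-area half-annuli, boundaries r_k = r_max√(k/N)
  (default N = 15). Filament length is assigned to rings by resampling
  polylines into ≤ 25 μm elements and binning midpoints (mass-conserving
  to <0.1%); tips are counted by position.
- **Bootstrap uncertainty.** Each ring is partitioned into equal-area
  radial–angular cells (the equal-area analogue of a rectangular tiling
  inside an annulus; default 10,000 cells), per-cell densities are
  resampled with replacement (default 100×), and the s.d. of the resampled
  mean is reported. Against a planar Poisson segment process the bootstrap
  s.d. matches the true sampling s.d. within ~10%.
- **Arrival times.** ρ(t) per ring is fitted with K₁/(1+e^{λ(t_n−t)}) and
  tip density with the derivative form K₂e^{λ(t'_n−t)}/(1+e^{λ(t'_n−t)})²;
  initial guesses K = max, λ = 4/(t₉₀−t₁₀), t_n = first half-max crossing;
  CIs by residual-resampling bootstrap (default 1,000×). Ring alignment
  uses the filament t_n, not the tip t'_n.
- **Wave speed** is the straight-line slope of front position against
  time, cross-checked three ways (arrival times per ring, hull-equivalent
  colony radius r = √(2A/π), mean puller-tip speed); they agree within
  10% on simulated colonies. Puller tips are growing tips that are convex
  hull vertices at two consecutive frames.
- **Classification.** BAS edge if length < 400 μm, or < 1,000 μm with a
  degree-1 endpoint, or width < 7 μm with width·length < 9,000 μm²; RH
  otherwise. Growing tip: degree-1 node displaced ≥ 40 px between frames
  (pixel pitch 3.25 μm/px by default, configurable). RH tip: net
  displacement > 2.5 mm.
- **α and β** come from zero-intercept regressions of the ring-binned
  branching rate on tip density and of the anastomosis rate on n·ρ, with
  ring-bootstrap CIs. α recovers to ±0.005. The β regression lands a
  factor 1.4–2 above the mechanistic β_eff because tip and filament
  densities covary azimuthally within a ring (ring means underestimate
  ⟨nρ⟩); the estimate is reported as the ring-frame observable it is.
- **ρ_A** (loop density) divides the Euler count e − v + c by total
  network length (per-area normalization available behind a flag); the
  Euler count includes fusions at crossing points, which tip tracking
  alone cannot see.

## Graph metrics (`graphmetrics`)

Betweenness counts one length-weighted shortest path per node to its
nearest root anchor (multi-source Dijkstra, deterministic node-id
tie-break). Geometric efficiency is the mean of Euclidean over
shortest-path distance — all node pairs up to 2,000 nodes, else 10⁵ seeded
pairs; root mode pairs each node with its nearest anchor. References are
the Euclidean MST (computed on the Delaunay edge set, which contains it)
and the Delaunay triangulation over the *same* node set (all snapshot
nodes by default); normalization X̂ = (X−X_MST)/(X_DT−X_MST) with carbon
cost C = γ·total length. BC tails are summarized by a log-binned histogram
and a continuous-power-law MLE above x_min (default: median), with a
log-likelihood comparison against an exponential tail.

## Flows (`flows`)

Kymographs are space×time images of a 20 μm line ROI (default 144 px,
20 fps). The tracer replaces the neural-network tool used on real videos
with a classical pipeline under the same constraints: background
subtraction, thresholding, Hough line detection, per-frame
intensity-weighted centroids, Theil–Sen slope, a minimum of 10 consecutive
frames, and a speed cap of the ROI length per 10 frames (40 μm/s at
20 fps). Immotile objects below 0.8 μm/s are excluded; the Stokes–Einstein
recomputation of that threshold (T = 298 K, η = 0.89 mPa·s, r = 35 nm,
Δt = 20 s) gives ≈ 0.6 μm/s, and both numbers are surfaced. Velocities
map to the network by snapping to the nearest edge (≤ 100 μm), then
walking toward the hypha's own tip following direction/width continuity at
junctions (a turn > 60° ends the hypha — e.g. at a fusion junction, where
no tip exists and d_tip is flagged). On simulator output the walk recovers
the ground-truth arclength exactly for live-tip hyphae.

## Problem sizes

Tests run colonies of 25–40 mm radius over 40–220 h (hundreds of trails,
10²–10³ events) and PDE grids of 5–50 μm over 60–200 h; these sizes keep
every estimator in its asymptotic regime while the whole suite stays
desk-scale.

## What the synthetic tests do not show

The generator emulates the statistical structure of tracked colonies —
constant front speed, low self-regulated density, BAS decoration, event
logs, bidirectional flows — but not image-level artefacts: broken tracks,
segmentation noise in widths, misaligned frames, curved-hypha width
estimation, or retraction (the model is growth-only). Passing the
reconciliation tests shows the estimators are exact on clean tracked
graphs, not that they are robust to extraction errors. Widths are
generated, not measured; the width–BC correlation is therefore exercised
with constructed width fields only.
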