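# mycowave

Quantitative analysis of how arbuscular-mycorrhizal (AM) fungal colonies
grow and trade: travelling-wave range expansion of the hyphal network,
its graph topology, and the bidirectional cytoplasmic flows inside it.

AM fungi are obligate symbionts that exchange soil phosphorus for host
carbon through a planar network of hyphae. Time-resolved imaging of such
networks shows a striking regularity: a pulse of growing tips advances at
constant speed, leaving behind hyphal filament that saturates at a low,
spatially constant density. `mycowave` implements the full analysis stack
for this phenomenon:

- **`barewave`** — the branching/annihilating range-expansion (BARE) wave
  model, two coupled PDEs for tip density *n* (mm⁻²) and filament density
  *ρ* (μm mm⁻²):

  ```
  ∂n/∂t = α n − β n ρ + ∇·J,   J = D_n ∇n − v n r̂
  ∂ρ/∂t = v n
  ```

  Tips branch at rate α, annihilate on existing filament (anastomosis) at
  rate βρ, and advect outward at the apical growth speed *v*. The front is
  a *pulled* wave moving at c ≈ v, and the wake balance αρ_sat = βρ_sat²/2
  pins the saturation density at ρ_sat = 2α/β. An optional third field
  models diffusion-limited phosphorus uptake and the carbon cost per unit
  phosphorus acquired.
- **`colonysim`** — an off-lattice agent-based generator of synthetic
  colonies (tips advect, branch, fuse or cross; BAS decoration, spores,
  per-edge ground-truth flow speeds) that produces the same tracked-graph
  data structures as the imaging pipeline, with an exact event log.
- **`netmodel`** — the time-resolved spatial graph data model, CSV/GraphML
  I/O, snapshots, and the Euler loop count e − v + c (cumulative
  anastomosis count of a planar network).
- **`waveprofile`** — equal-area half-annulus ring frames, filament/tip
  densities with spatial-bootstrap uncertainties, logistic arrival-time
  fits, wavefront speed, colony radius and puller-tip identification.
- **`events`** — tracker-style classification (BAS vs runner hyphae,
  growing tips) and event detection (branching, anastomosis, crossing),
  ring-binned rates, and recovery of α and β by zero-intercept regression.
- **`graphmetrics`** — betweenness centrality to the root compartment,
  global/root geometric transport efficiencies, minimum-spanning-tree and
  Delaunay reference networks, and MST/DT-normalized efficiency and cost.
- **`flows`** — kymograph synthesis and classical trajectory tracing
  (Hough ridge detection + Theil-Sen slopes), immotile filtering, the
  diffusion length L = 2D/v_g, and linear fits of flow speed against
  distance-to-tip and betweenness.

## Worked example

```python
import numpy as np
from mycowave import barewave as bw
from mycowave import colonysim as cs, events as evm, netmodel as nm

# 1. the continuum wave at the measured parameters
params = bw.BAREParams(alpha_per_h=0.04, beta_um_per_h=23.0,
                       v_um_per_h=280.0, dr_um=5.0, r_max_mm=60.0,
                       t_max_h=200.0)
sol = bw.integrate_bare(params)
c, rho_sat, width = bw.measure_wave(sol)
print(f"front speed c = {c:.1f} um/h, rho_sat = {rho_sat:.0f} um/mm2")

# 2. a synthetic colony, and the detectors run against its ground truth
sim = cs.SimParams(t_max_h=60, roi_radius_mm=25, n_anchors=5, seed=4)
series, truth, report = cs.simulate_colony(sim)
detected = evm.detect_anastomoses(series)
print(f"anastomoses detected {len(detected)} / simulated {report.n_anastomoses}")
```

prints

```
front speed c = 284.1 um/h, rho_sat = 3473 um/mm2
anastomoses detected 22 / simulated 22
```

The front speed equals the tip advection speed of 280 μm/h to within the
numerical-diffusion correction of the first-order upwind scheme (~1.5%),
demonstrating the pulled-wave property; ρ_sat lands on the wake balance
2α/β = 3478 μm mm⁻² to 0.2%; and the tracker-style detector reproduces the
simulator's anastomosis log exactly.

There is also a CLI for file-based workflows:

```bash
mycowave simulate --seed 1 --out colony/     # writes the CSV bundle
mycowave pde --out wave.npz                  # integrates the wave model
mycowave report --seed 1 --out run/          # end-to-end pipeline
```

## Layout

```
src/mycowave/       library (one module per analysis stage)
tests/              pytest suite, incl. ground-truth reconciliation
scripts/acceptance.py
docs/methods.md     model, estimators, numerical choices, limitations
```
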