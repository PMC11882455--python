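"""Numerical integration of the branching/annihilating range-expansion PDEs.

The model couples a growing-tip density n (mm^-2) to a hyphal filament
density rho (μm mm^-2)::

    dn/dt   = alpha*n - beta*n*rho + div(J),   J = D_n grad(n) - v n r_hat
    drho/dt = v*n

Tips multiply by branching at rate alpha, annihilate on existing filament
at rate beta*rho, and advect outward at the apical growth speed v with a
small diffusive spread D_n.  The resulting solution is a pulled travelling
wave: the front moves at c ≈ v + 2*sqrt(alpha*D_n) (≈ v for small D_n), and
the filament density saturates behind the front at the branching/
annihilation balance rho_sat = 2*alpha/beta.

An optional third field [P] models diffusion-limited phosphorus uptake::

    dP/dt = D_P lap(P) - k_up * rho * P

with the absorbed amount recorded as a flux field, so that total phosphorus
(medium + absorbed) is conserved and a depletion front co-propagates with
the filament wave.

Discretization: conservative first-order upwind advection, explicit
centred diffusion, forward Euler in time; monotone and positivity
preserving under the validated CFL bound.  Internally lengths are in mm and
times in hours; the public API uses the measurement units (μm where noted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BAREParams",
    "WaveSolution",
    "integrate_bare",
    "integrate_bare_phosphorus",
    "measure_wave",
    "cost_per_phosphorus",
]

_UM_PER_MM2_TO_PER_MM = 1e-3  # μm mm^-2 -> mm mm^-2 (= mm^-1)


@dataclass
class BAREParams:
    alpha_per_h: float = 0.04
    beta_um_per_h: float = 23.0
    v_um_per_h: float = 280.0
    D_n_um2_per_h: float = 25.0
    geometry: str = "cartesian-1d"  # or "radial-1d"
    r_max_mm: float = 60.0
    dr_um: float = 5.0
    dt_h: float | None = None  # None -> 0.9 x the CFL limit
    t_max_h: float = 200.0
    save_every_h: float = 2.0
    # phosphorus extension
    k_up_mm_per_h: float = 0.015
    D_P_um2_per_h: float = 3600.0
    P0: float = 1.0
    carbon_cost_per_um: float = 1.0

    def __post_init__(self):
        for name in ("alpha_per_h", "beta_um_per_h", "v_um_per_h", "D_n_um2_per_h",
                     "r_max_mm", "dr_um", "t_max_h", "k_up_mm_per_h",
                     "D_P_um2_per_h", "P0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.geometry not in ("cartesian-1d", "radial-1d"):
            raise ValueError("geometry must be 'cartesian-1d' or 'radial-1d'")

    def cfl_dt(self, with_P: bool = False) -> float:
        """Largest stable forward-Euler step for the chosen grid."""
        dr_mm = self.dr_um / 1000.0
        v = self.v_um_per_h / 1000.0
        D = self.D_n_um2_per_h / 1e6
        # in radial geometry the innermost cell sees face/centre radius
        # ratios up to 2, tightening the stability bound by that factor
        geo = 2.0 if self.geometry == "radial-1d" else 1.0
        denom = geo * (v / dr_mm + 2.0 * D / dr_mm**2)
        if with_P:
            denom = max(denom, geo * 2.0 * (self.D_P_um2_per_h / 1e6) / dr_mm**2)
        if denom <= 0:
            return self.t_max_h
        return 1.0 / denom


@dataclass
class WaveSolution:
    r_mm: np.ndarray
    t_h: np.ndarray
    n: np.ndarray  # (n_t, n_r), mm^-2
    rho: np.ndarray  # (n_t, n_r), μm mm^-2
    P: np.ndarray | None = None
    P_flux: np.ndarray | None = None  # instantaneous uptake rate field
    P_absorbed: np.ndarray | None = None  # cumulative absorbed P per time
    params: BAREParams | None = None
    extras: dict = field(default_factory=dict)


def _default_init(nr: int, dr_mm: float):
    n0 = np.zeros(nr)
    pulse = max(3, int(0.25 / dr_mm))  # 250 μm pulse of tips at the origin
    n0[:pulse] = 1.0
    return n0, np.zeros(nr)


def _integrate(params: BAREParams, init=None, with_P: bool = False) -> WaveSolution:
    dr = params.dr_um / 1000.0  # mm
    nr = int(round(params.r_max_mm / dr))
    r = (np.arange(nr) + 0.5) * dr
    v = params.v_um_per_h / 1000.0
    D = params.D_n_um2_per_h / 1e6
    alpha = params.alpha_per_h
    beta = params.beta_um_per_h * _UM_PER_MM2_TO_PER_MM  # acts on rho in mm^-1

    dt = params.dt_h
    limit = params.cfl_dt(with_P=with_P)
    if dt is None:
        dt = 0.9 * limit
    elif dt > limit:
        raise ValueError(
            f"dt_h={dt} violates the CFL bound; maximum stable step is {limit:.3g} h"
        )

    if init is None:
        n, rho = _default_init(nr, dr)
    else:
        n = np.array(init[0], dtype=float)
        rho = np.array(init[1], dtype=float) * _UM_PER_MM2_TO_PER_MM
        if len(n) != nr or len(rho) != nr:
            raise ValueError("init fields do not match the grid")

    radial = params.geometry == "radial-1d"
    if radial:
        r_face = np.arange(1, nr) * dr  # interior faces
    P = np.full(nr, params.P0) if with_P else None
    kup = params.k_up_mm_per_h
    DP = params.D_P_um2_per_h / 1e6

    n_steps = int(round(params.t_max_h / dt))
    save_stride = max(1, int(round(params.save_every_h / dt)))
    ts, ns, rhos, Ps, fluxes, absorbed = [], [], [], [], [], []
    cum_absorbed = 0.0

    def record(t):
        ts.append(t)
        ns.append(n.copy())
        rhos.append(rho.copy() / _UM_PER_MM2_TO_PER_MM)
        if with_P:
            Ps.append(P.copy())
            fluxes.append(kup * rho * P)
            absorbed.append(cum_absorbed)

    record(0.0)
    for step in range(1, n_steps + 1):
        # advective flux at interior faces (upwind, v >= 0: donor is the left cell)
        F = v * n[:-1]
        if radial:
            div_adv = np.zeros(nr)
            div_adv[1:] += r_face * F / (r[1:] * dr)
            div_adv[:-1] -= r_face * F / (r[:-1] * dr)
            Fd = D * (n[1:] - n[:-1]) / dr
            div_diff = np.zeros(nr)
            div_diff[:-1] += r_face * Fd / (r[:-1] * dr)
            div_diff[1:] -= r_face * Fd / (r[1:] * dr)
        else:
            div_adv = np.zeros(nr)
            div_adv[1:] += F / dr
            div_adv[:-1] -= F / dr
            Fd = D * (n[1:] - n[:-1]) / dr
            div_diff = np.zeros(nr)
            div_diff[:-1] += Fd / dr
            div_diff[1:] -= Fd / dr

        react = alpha * n - beta * n * rho
        n_new = n + dt * (react + div_adv + div_diff)
        rho_new = rho + dt * v * n

        if with_P:
            FP = DP * (P[1:] - P[:-1]) / dr
            divP = np.zeros(nr)
            if radial:
                divP[:-1] += r_face * FP / (r[:-1] * dr)
                divP[1:] -= r_face * FP / (r[1:] * dr)
            else:
                divP[:-1] += FP / dr
                divP[1:] -= FP / dr
            uptake = kup * rho * P
            P_new = P + dt * (divP - uptake)
            if radial:
                cum_absorbed += dt * float(np.sum(uptake * r * dr))
            else:
                cum_absorbed += dt * float(np.sum(uptake * dr))
            P = P_new

        if np.any(n_new < -1e-9) or np.any(rho_new < -1e-12):
            raise FloatingPointError(
                f"negative field at step {step} (t={step * dt:.2f} h): "
                "integration unstable, reduce dt or refine the grid"
            )
        n, rho = np.maximum(n_new, 0.0), rho_new
        if step % save_stride == 0:
            record(step * dt)

    sol = WaveSolution(
        r_mm=r,
        t_h=np.asarray(ts),
        n=np.asarray(ns),
        rho=np.asarray(rhos),
        P=np.asarray(Ps) if with_P else None,
        P_flux=np.asarray(fluxes) if with_P else None,
        P_absorbed=np.asarray(absorbed) if with_P else None,
        params=params,
    )
    return sol


def integrate_bare(params: BAREParams, init=None) -> WaveSolution:
    """Integrate the two-field tip/filament system.

    ``init`` is an optional pair ``(n0, rho0)`` on the cell-centre grid
    (units mm^-2 and μm mm^-2); by default a compact pulse of tips sits at
    the origin on an empty substrate.
    """
    return _integrate(params, init=init, with_P=False)


def integrate_bare_phosphorus(params: BAREParams, init=None) -> WaveSolution:
    """Integrate tips/filament plus the diffusion-limited phosphorus field."""
    return _integrate(params, init=init, with_P=True)


def _front_positions(sol: WaveSolution, level: float):
    """Half-maximum crossing radius of rho for every saved time."""
    out = np.full(len(sol.t_h), np.nan)
    for i, prof in enumerate(sol.rho):
        above = prof >= level
        if not above.any() or above.all():
            continue
        # last index above the level, linear interpolation to the crossing
        j = int(np.where(above)[0][-1])
        if j + 1 >= len(prof):
            continue
        y0, y1 = prof[j], prof[j + 1]
        frac = (y0 - level) / max(y0 - y1, 1e-30)
        out[i] = sol.r_mm[j] + frac * (sol.r_mm[j + 1] - sol.r_mm[j])
    return out


def measure_wave(sol: WaveSolution) -> tuple[float, float, float]:
    """Extract (front speed c [μm/h], rho_sat [μm mm^-2], front width [mm]).

    The front position at each saved time is where the filament density
    crosses half of its plateau value; the speed is the slope of a linear
    fit over the last half of the run.  The plateau is averaged well behind
    the final front.
    """
    rho_end = sol.rho[-1]
    peak = float(rho_end.max())
    if peak <= 0:
        raise ValueError("no filament density developed; nothing to measure")
    pos = _front_positions(sol, 0.5 * peak)
    ok = np.isfinite(pos)
    if ok.sum() < 4:
        raise ValueError("no travelling front found (flat or boundary-limited run)")
    final_front = pos[ok][-1]
    if final_front > 0.95 * sol.r_mm[-1]:
        raise ValueError(
            "front reached the domain boundary; increase r_max_mm"
        )
    # plateau: just behind the final front, where the wake has matured to
    # its travelling-wave value (the early wake near the origin still
    # carries the start-up transient)
    sel = (sol.r_mm > 0.85 * final_front) & (sol.r_mm < 0.97 * final_front)
    if not sel.any():
        raise ValueError("domain too small to measure the plateau")
    rho_sat = float(rho_end[sel].mean())

    pos2 = _front_positions(sol, 0.5 * rho_sat)
    ok = np.isfinite(pos2)
    t_sel = sol.t_h >= sol.t_h[-1] / 2.0
    use = ok & t_sel
    if use.sum() < 4:
        raise ValueError("too few front positions in the fitting window")
    slope, _ = np.polyfit(sol.t_h[use], pos2[use], 1)
    c_um_h = float(slope * 1000.0)

    # front width: 10%-90% distance of the final profile
    lo = _front_positions(sol, 0.9 * rho_sat)[-1]
    hi = _front_positions(sol, 0.1 * rho_sat)[-1]
    width = float(hi - lo) if np.isfinite(lo) and np.isfinite(hi) else float("nan")
    return c_um_h, rho_sat, width


def cost_per_phosphorus(sol: WaveSolution, params: BAREParams | None = None) -> np.ndarray:
    """Carbon cost of built network per unit phosphorus absorbed, over time.

    Cost is gamma times the total filament length in the domain; the
    denominator is the cumulative absorbed phosphorus.  Times with no
    absorption yet are flagged as NaN.
    """
    if sol.P_absorbed is None:
        raise ValueError("requires a phosphorus-coupled solution")
    p = params or sol.params
    gamma = p.carbon_cost_per_um
    dr = float(sol.r_mm[1] - sol.r_mm[0])
    radial = (p.geometry == "radial-1d")
    if radial:
        weights = sol.r_mm * dr  # per unit angle
    else:
        weights = np.full_like(sol.r_mm, dr)
    total_len_um = (sol.rho * weights).sum(axis=1)  # μm per unit transverse extent
    absorbed = np.asarray(sol.P_absorbed)
    out = np.full(len(sol.t_h), np.nan)
    nz = absorbed > 0
    out[nz] = gamma * total_len_um[nz] / absorbed[nz]
    return out
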