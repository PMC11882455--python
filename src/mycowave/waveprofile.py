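"""Ring-frame density profiles, sigmoid arrival-time fits and wave metrics.

Densities of growing tips (mm^-2) and hyphal filament (μm mm^-2) are
spatially averaged in concentric equal-area half-annuli centred at the
colony base.  Per-ring time series are fitted with a logistic sigmoid
(filament) and its derivative (tips); the half-maximum time is the wave's
arrival time at that ring, and the slope of front position against time is
the wave speed.  Uncertainties come from spatial bootstrap over equal-area
cells within each ring and from residual-resampling bootstrap of the fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import ConvexHull

from . import constants
from .netmodel import NetworkSeries, snapshot

__all__ = [
    "RingFrame",
    "DensityProfiles",
    "SigmoidFit",
    "make_rings",
    "ring_densities",
    "bootstrap_density_sd",
    "colony_radius",
    "fit_sigmoid_rho",
    "fit_sigmoid_tip",
    "wavefront_speed",
    "saturating_density_vs_radius",
    "puller_tips",
]


@dataclass
class RingFrame:
    """Concentric equal-area half-annuli over the fungal half-plane."""

    origin: tuple[float, float]  # μm
    r_max_mm: float
    n_rings: int
    boundaries_mm: np.ndarray  # (n_rings + 1,) with boundaries_mm[0] == 0

    @property
    def area_mm2(self) -> float:
        return math_pi_half() * self.r_max_mm**2 / self.n_rings

    @property
    def centers_mm(self) -> np.ndarray:
        return 0.5 * (self.boundaries_mm[:-1] + self.boundaries_mm[1:])


def math_pi_half() -> float:
    return np.pi / 2.0


def make_rings(origin: tuple[float, float], r_max_mm: float,
               n_rings: int = constants.N_RINGS) -> RingFrame:
    """Equal-area half-annuli: boundaries r_k = r_max * sqrt(k / N)."""
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    if r_max_mm <= 0:
        raise ValueError("r_max_mm must be > 0")
    k = np.arange(n_rings + 1)
    return RingFrame(
        origin=tuple(origin),
        r_max_mm=float(r_max_mm),
        n_rings=int(n_rings),
        boundaries_mm=r_max_mm * np.sqrt(k / n_rings),
    )


@dataclass
class DensityProfiles:
    rings: RingFrame
    t_h: np.ndarray  # (n_t,)
    rho: np.ndarray  # (n_t, n_rings) filament density, μm mm^-2
    n_tips: np.ndarray  # (n_t, n_rings) tip density, mm^-2
    rho_sd: np.ndarray | None = None
    n_sd: np.ndarray | None = None
    arrival_t_h: np.ndarray | None = None  # per ring, from sigmoid fits
    extras: dict = field(default_factory=dict)


def _resample_polyline(poly: np.ndarray, max_seg_um: float = 25.0):
    """Midpoints and lengths of sub-segments no longer than ``max_seg_um``."""
    mids, lens = [], []
    for a, b in zip(poly[:-1], poly[1:]):
        seg = np.hypot(*(b - a))
        if seg <= 0:
            continue
        n_sub = max(1, int(np.ceil(seg / max_seg_um)))
        fr = (np.arange(n_sub) + 0.5) / n_sub
        mids.append(a[None, :] + fr[:, None] * (b - a)[None, :])
        lens.append(np.full(n_sub, seg / n_sub))
    if not mids:
        return np.empty((0, 2)), np.empty(0)
    return np.vstack(mids), np.concatenate(lens)


def _snapshot_length_elements(series: NetworkSeries, t: float, origin,
                              rh_only: bool = True):
    """(r_mm, theta, length_um) of short filament elements at time t."""
    g = snapshot(series, t)
    rs, ths, ls = [], [], []
    for _, _, data in g.edges(data=True):
        if rh_only and data["label"] != "RH":
            continue
        mids, lens = _resample_polyline(np.asarray(data["polyline"], dtype=float))
        if len(lens) == 0:
            continue
        dx = mids[:, 0] - origin[0]
        dy = mids[:, 1] - origin[1]
        rs.append(np.hypot(dx, dy) / 1000.0)
        ths.append(np.arctan2(dy, dx))
        ls.append(lens)
    if not rs:
        return np.empty(0), np.empty(0), np.empty(0)
    return np.concatenate(rs), np.concatenate(ths), np.concatenate(ls)


def ring_densities(series: NetworkSeries, rings: RingFrame,
                   tip_filter: dict[float, list[int]] | None = None,
                   rh_only: bool = True) -> DensityProfiles:
    """Per-ring filament and growing-tip densities for every timepoint.

    ``tip_filter`` maps each timepoint to the node ids to count as growing
    (RH) tips, normally the output of :func:`mycowave.events.growing_tips`
    restricted to runner hyphae; by default all currently growing trail
    tips are used.
    """
    n_t = len(series.timepoints)
    rho = np.zeros((n_t, rings.n_rings))
    ntip = np.zeros((n_t, rings.n_rings))
    bnds = rings.boundaries_mm
    area = rings.area_mm2
    if not series.trails:
        warnings.warn("empty series: density profiles are all zero", stacklevel=2)

    for i, t in enumerate(series.timepoints):
        r, _, lens = _snapshot_length_elements(series, t, rings.origin, rh_only)
        if len(r):
            idx = np.searchsorted(bnds, r, side="right") - 1
            ok = (idx >= 0) & (idx < rings.n_rings)
            np.add.at(rho[i], idx[ok], lens[ok])
        if tip_filter is not None:
            ids = tip_filter.get(float(t), [])
            for nid in ids:
                st = series.node_state(nid, t)
                if st is None:
                    continue
                rr = np.hypot(st[0] - rings.origin[0], st[1] - rings.origin[1]) / 1000.0
                k = int(np.searchsorted(bnds, rr, side="right")) - 1
                if 0 <= k < rings.n_rings:
                    ntip[i, k] += 1
        else:
            for tr in series.trails.values():
                if rh_only and tr.label != "RH":
                    continue
                k_idx = int(np.searchsorted(tr.times, t + 1e-9)) - 1
                if k_idx < 0 or tr.times[-1] < t - 1e-9:  # not born yet or stopped
                    continue
                x, y = tr.verts[k_idx]
                rr = np.hypot(x - rings.origin[0], y - rings.origin[1]) / 1000.0
                k = int(np.searchsorted(bnds, rr, side="right")) - 1
                if 0 <= k < rings.n_rings:
                    ntip[i, k] += 1
    rho /= area
    ntip /= area
    return DensityProfiles(rings=rings, t_h=series.timepoints.copy(),
                           rho=rho, n_tips=ntip)


def bootstrap_density_sd(
    series: NetworkSeries,
    rings: RingFrame,
    ring_index: int,
    t: float,
    n_cells: int = constants.BOOTSTRAP_N_CELLS,
    n_boot: int = constants.BOOTSTRAP_N_RESAMPLES,
    seed: int = 0,
    rh_only: bool = True,
) -> float:
    """Bootstrap s.d. of the mean filament density within one ring.

    The half-annulus is partitioned into ``n_cells`` equal-area
    radial-angular cells (the closest equal-area analogue of a rectangular
    tiling inside an annulus); per-cell densities are resampled with
    replacement ``n_boot`` times and the s.d. of the resampled mean is
    returned.
    """
    rng = np.random.default_rng(seed)
    r0, r1 = rings.boundaries_mm[ring_index], rings.boundaries_mm[ring_index + 1]
    # choose an aspect-balanced cell grid
    n_theta = max(1, int(round(np.sqrt(n_cells))))
    n_r = max(1, int(round(n_cells / n_theta)))
    n_cells_eff = n_r * n_theta
    r_bnds = np.sqrt(r0**2 + (r1**2 - r0**2) * np.arange(n_r + 1) / n_r)

    r, th, lens = _snapshot_length_elements(series, t, rings.origin, rh_only)
    sel = (r >= r0) & (r < r1)
    cell_len = np.zeros(n_cells_eff)
    if sel.any():
        ri = np.clip(np.searchsorted(r_bnds, r[sel], side="right") - 1, 0, n_r - 1)
        ti = np.clip(((th[sel] / np.pi) * n_theta).astype(int), 0, n_theta - 1)
        np.add.at(cell_len, ri * n_theta + ti, lens[sel])
    cell_area = rings.area_mm2 / n_cells_eff
    cell_density = cell_len / cell_area
    means = np.empty(n_boot)
    for b in range(n_boot):
        means[b] = rng.choice(cell_density, size=n_cells_eff, replace=True).mean()
    return float(means.std(ddof=1))


def colony_radius(series_or_points, t: float | None = None) -> float:
    """Colony radius from the semicircle-equivalent convex-hull area.

    ``r = sqrt(2 A / pi)`` where A is the convex hull area of all node
    positions (mm).  Accepts a NetworkSeries plus a timepoint, or an
    (N, 2) array of positions in μm.
    """
    if isinstance(series_or_points, NetworkSeries):
        g = snapshot(series_or_points, t)
        pts = np.array([g.nodes[n]["pos"] for n in g.nodes if "pos" in g.nodes[n]])
    else:
        pts = np.asarray(series_or_points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 nodes for a convex hull")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # qhull degenerate input
        raise ValueError(f"degenerate node configuration: {exc}") from exc
    area_mm2 = hull.volume / 1e6  # 2-D hull: .volume is the area (μm^2)
    return float(np.sqrt(2.0 * area_mm2 / np.pi))


# ---------------------------------------------------------------------------
# sigmoid fits and arrival times
# ---------------------------------------------------------------------------

@dataclass
class SigmoidFit:
    K: float
    lambda_per_h: float
    t_n_h: float
    cov: np.ndarray | None
    ok: bool
    t_n_ci: tuple[float, float] | None = None
    message: str = ""


def _sigmoid_rho(t, K1, lam, tn):
    return K1 / (1.0 + np.exp(np.clip(lam * (tn - t), -500, 500)))


def _sigmoid_tip(t, K2, lam, tn):
    e = np.exp(np.clip(lam * (tn - t), -250, 250))
    return K2 * e / (1.0 + e) ** 2


def _initial_guess(t, y):
    K = float(np.max(y))
    y10, y90 = 0.1 * K, 0.9 * K
    t10 = t[np.argmax(y >= y10)]
    t90 = t[np.argmax(y >= y90)]
    lam = 4.0 / max(t90 - t10, (t[1] - t[0]))
    tn = t[np.argmax(y >= 0.5 * K)]  # first crossing of half max
    return K, lam, tn


def _fit(model, t, y, n_boot, seed, p0=None):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(y == 0):
        raise ValueError("all-zero series cannot be fitted")
    if y[-1] < y[0] and np.max(y) <= y[0]:
        raise ValueError("monotone-decreasing series: no rising front to fit")
    if np.max(y) < 2.0 * max(np.min(y), 1e-12) and model is _sigmoid_rho:
        raise ValueError("series does not span the density rise (max < 2x min)")
    if p0 is None:
        p0 = _initial_guess(t, y)
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except Exception as exc:
        return SigmoidFit(np.nan, np.nan, np.nan, None, False, message=str(exc))
    if popt[1] <= 0:
        return SigmoidFit(*popt, cov=pcov, ok=False, message="non-positive rate")
    tn_ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        resid = y - model(t, *popt)
        tns = []
        for _ in range(n_boot):
            yb = model(t, *popt) + rng.choice(resid, size=len(resid), replace=True)
            try:
                pb, _ = curve_fit(model, t, yb, p0=popt, maxfev=5000)
                tns.append(pb[2])
            except Exception:
                continue
        if len(tns) >= max(10, n_boot // 2):
            tn_ci = tuple(np.percentile(tns, [2.5, 97.5]))
    return SigmoidFit(K=float(popt[0]), lambda_per_h=float(popt[1]),
                      t_n_h=float(popt[2]), cov=pcov, ok=True, t_n_ci=tn_ci)


def fit_sigmoid_rho(t, rho, n_boot: int = constants.SIGMOID_BOOTSTRAP_N,
                    seed: int = 0) -> SigmoidFit:
    """Fit rho(t) = K1 / (1 + exp(lambda (t_n - t))); t_n is the arrival time."""
    return _fit(_sigmoid_rho, t, rho, n_boot, seed)


def fit_sigmoid_tip(t, n, n_boot: int = constants.SIGMOID_BOOTSTRAP_N,
                    seed: int = 0) -> SigmoidFit:
    """Fit the tip pulse n(t) = K2 e^{lambda(t'_n - t)} / (1+e^{lambda(t'_n - t)})^2."""
    t = np.asarray(t, dtype=float)
    n = np.asarray(n, dtype=float)
    K = 4.0 * float(np.max(n))  # peak of the pulse is K2/4
    tn = float(t[np.argmax(n)])
    nz = n > 0.1 * np.max(n)
    spread = max(t[nz][-1] - t[nz][0], t[1] - t[0]) if nz.any() else t[1] - t[0]
    return _fit(_sigmoid_tip, t, n, n_boot, seed, p0=(K, 4.0 / spread, tn))


def arrival_times(profiles: DensityProfiles, n_boot: int = 200,
                  seed: int = 0) -> list[SigmoidFit]:
    """Sigmoid arrival-time fit of the filament density in every ring."""
    fits = []
    for k in range(profiles.rings.n_rings):
        y = profiles.rho[:, k]
        try:
            fits.append(fit_sigmoid_rho(profiles.t_h, y, n_boot=n_boot,
                                        seed=seed + k))
        except ValueError as exc:
            fits.append(SigmoidFit(np.nan, np.nan, np.nan, None, False,
                                   message=str(exc)))
    profiles.arrival_t_h = np.array([f.t_n_h if f.ok else np.nan for f in fits])
    return fits


def wavefront_speed(positions_mm, t_h, n_boot: int = 1000,
                    seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Front speed (μm/h) as the slope of front position vs time, with CI."""
    pos = np.asarray(positions_mm, dtype=float)
    t = np.asarray(t_h, dtype=float)
    ok = np.isfinite(pos) & np.isfinite(t)
    pos, t = pos[ok], t[ok]
    if len(pos) < 4:
        raise ValueError("need at least 4 front positions")
    slope, icpt = np.polyfit(t, pos, 1)
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(pos), len(pos))
        if len(np.unique(t[idx])) < 2:
            continue
        slopes.append(np.polyfit(t[idx], pos[idx], 1)[0])
    ci = tuple(1000.0 * np.percentile(slopes, [2.5, 97.5])) if slopes else (np.nan,) * 2
    return float(slope * 1000.0), ci


def saturating_density_vs_radius(fits: list[SigmoidFit], rings: RingFrame,
                                 n_boot: int = 1000, seed: int = 0):
    """Linear fit of the per-ring plateau density K1 against ring radius.

    A near-zero slope indicates a spatially constant saturation density,
    the signature of anastomosis-regulated growth.
    Returns (slope, intercept, slope CI) with densities in μm mm^-2 and
    radii in mm; failed ring fits are excluded with a warning.
    """
    r = rings.centers_mm
    K = np.array([f.K if f.ok else np.nan for f in fits])
    ok = np.isfinite(K)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 rings with successful fits")
    if ok.sum() < len(K):
        warnings.warn(f"excluding {int((~ok).sum())} failed ring fit(s)", stacklevel=2)
    r, K = r[ok], K[ok]
    slope, icpt = np.polyfit(r, K, 1)
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(r), len(r))
        if len(np.unique(r[idx])) < 2:
            continue
        slopes.append(np.polyfit(r[idx], K[idx], 1)[0])
    ci = tuple(np.percentile(slopes, [2.5, 97.5])) if slopes else (np.nan, np.nan)
    return float(slope), float(icpt), ci


def puller_tips(series: NetworkSeries, t: float,
                growing: dict[float, list[int]] | None = None):
    """Growing tips sitting on the colony's convex hull at t and t+1.

    Returns (tip ids, mean puller speed μm/h).  The speed is the mean
    frame-to-frame displacement rate of the puller tips.
    """
    tps = series.timepoints
    i = int(np.argmin(np.abs(tps - t)))
    if i + 1 >= len(tps):
        raise ValueError("t must have a following timepoint")
    t0, t1 = tps[i], tps[i + 1]

    if growing is None:
        from .events import growing_tips  # local import to avoid a cycle
        growing = growing_tips(series)
    tips0 = set(growing.get(float(t0), [])) & set(growing.get(float(t1), []))
    if len(tips0) < 3:
        warnings.warn("fewer than 3 growing tips: returning all of them",
                      stacklevel=2)
        ids = sorted(tips0)
    else:
        ids = []
        hulls = {}
        for tt in (t0, t1):
            g = snapshot(series, tt)
            pts = np.array([g.nodes[n]["pos"] for n in g.nodes if "pos" in g.nodes[n]])
            names = [n for n in g.nodes if "pos" in g.nodes[n]]
            if len(pts) < 3:
                hulls[tt] = set(names)
                continue
            try:
                hull = ConvexHull(pts)
                hulls[tt] = {names[v] for v in hull.vertices}
            except Exception:
                hulls[tt] = set(names)
        ids = sorted(tips0 & hulls[t0] & hulls[t1])
    speeds = []
    for nid in ids:
        s0 = series.node_state(nid, t0)
        s1 = series.node_state(nid, t1)
        if s0 and s1:
            speeds.append(np.hypot(s1[0] - s0[0], s1[1] - s0[1]) / (t1 - t0))
    v_p = float(np.mean(speeds)) if speeds else np.nan
    return ids, v_p
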