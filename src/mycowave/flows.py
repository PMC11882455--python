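"""Kymograph synthesis, trajectory extraction and flow-velocity statistics.

A kymograph is a space-by-time intensity image of a 20 μm line region of
interest inside a hypha; a particle moving at constant speed traces a
straight line whose slope is its velocity (positive = tipward).  The
tracer here is classical: threshold, Hough-transform line detection, and a
Theil-Sen slope refinement on per-frame intensity centroids, subject to
the same constraints used on the imaging data (minimum ten consecutive
frames; speed cap of the ROI length over ten frames; immotile objects
below 0.8 μm/s excluded).

Velocities are mapped back to network position: the curvilinear distance
d_tip to the tip of the host hypha (following width/direction continuity
at junctions) and the betweenness centrality of the host edge, with
linear-fit-plus-bootstrap summaries of how each covariate modulates mean
tipward and rootward speeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import theilslopes
from skimage.transform import hough_line, hough_line_peaks

from . import constants

__all__ = [
    "Kymograph",
    "Trajectory",
    "FlowSample",
    "synthesize_kymograph",
    "extract_trajectories",
    "immotile_filter",
    "immotile_threshold_um_s",
    "velocity_stats",
    "diffusion_length_mm",
    "map_flow_to_network",
    "flow_gradient_fits",
    "save_kymograph",
    "load_kymograph",
]


@dataclass
class Kymograph:
    """Space (rows) by time (columns) intensity array with calibration."""

    image: np.ndarray  # uint16 or float, shape (n_space, n_time)
    dx_um: float
    dt_s: float
    meta: dict = field(default_factory=dict)

    @property
    def roi_length_um(self) -> float:
        return self.image.shape[0] * self.dx_um

    @property
    def duration_s(self) -> float:
        return self.image.shape[1] * self.dt_s

    def speed_cap_um_s(self, min_frames: int = constants.TRAJECTORY_MIN_FRAMES) -> float:
        """Fastest reliably traceable speed: the ROI traversed in
        ``min_frames`` frames (40 μm/s at 20 fps, 50 μm/s at 25 fps)."""
        return self.roi_length_um / (min_frames * self.dt_s)


@dataclass
class Trajectory:
    velocity_um_s: float  # signed; + tipward, - rootward
    t0_s: float
    duration_frames: int
    n_points: int


@dataclass
class FlowSample:
    """Velocity statistics of one video position mapped onto the network."""

    x_um: float
    y_um: float
    d_tip_mm: float
    bc: float
    velocities_um_s: np.ndarray
    edge_id: object = None
    alignment_error_um: float = 0.0


def synthesize_kymograph(
    particles,
    n_space: int = 144,
    n_time: int = 400,
    dx_um: float = constants.KYMOGRAPH_ROI_LENGTH_UM / 144,
    dt_s: float = 1.0 / 20.0,
    noise_sd: float = 40.0,
    background: float = 800.0,
    amplitude: float = 600.0,
    psf_px: float = 1.2,
    seed: int = 0,
) -> Kymograph:
    """Render particle tracks into a 16-bit kymograph, plus Gaussian noise.

    ``particles`` is a list of dicts with keys ``v_um_s`` (signed speed),
    ``x0_um`` (position at entry), ``t0_s`` (entry time) and optionally
    ``intensity`` (relative amplitude).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    img = rng.normal(background, noise_sd, size=(n_space, n_time))
    rows = np.arange(n_space)
    for p in particles:
        v = float(p["v_um_s"])
        x0 = float(p.get("x0_um", 0.0 if v >= 0 else (n_space - 1) * dx_um))
        t0 = float(p.get("t0_s", 0.0))
        amp = amplitude * float(p.get("intensity", 1.0))
        for j in range(n_time):
            t = j * dt_s
            if t < t0:
                continue
            x = (x0 + v * (t - t0)) / dx_um
            if x < -3 or x > n_space + 3:
                continue
            img[:, j] += amp * np.exp(-0.5 * ((rows - x) / psf_px) ** 2)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return Kymograph(image=img, dx_um=dx_um, dt_s=dt_s,
                     meta={"seed": seed, "n_particles": len(particles)})


def save_kymograph(kymo: Kymograph, path: str | Path) -> Path:
    """Write the 16-bit TIFF plus its JSON calibration sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, kymo.image.astype(np.uint16))
    sidecar = dict(dx_um=kymo.dx_um, dt_s=kymo.dt_s, **kymo.meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))
    return path


def load_kymograph(path: str | Path) -> Kymograph:
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    img = tifffile.imread(path)
    return Kymograph(image=img, dx_um=float(meta.pop("dx_um")),
                     dt_s=float(meta.pop("dt_s")), meta=meta)


def extract_trajectories(
    kymo: Kymograph,
    min_frames: int = constants.TRAJECTORY_MIN_FRAMES,
    threshold_sd: float = 2.0,
    band_px: float = 2.5,
    max_lines: int = 30,
) -> list[Trajectory]:
    """Detect straight particle tracks and their signed velocities.

    Pipeline: background-subtract, threshold, Hough line detection, then
    per-candidate refinement: collect bright pixels in a band around the
    line, reduce to one position per frame, require at least ``min_frames``
    consecutive frames, and fit the velocity with a robust Theil-Sen
    slope.  Tracks faster than the reliability cap are discarded.
    """
    img = kymo.image.astype(float)
    bg = np.median(img)
    sd = img.std()
    if sd < 1e-9:
        warnings.warn("flat kymograph: no trajectories", stacklevel=2)
        return []
    work = img - bg
    mask = work > threshold_sd * sd
    if not mask.any():
        return []

    theta = np.linspace(-np.pi / 2, np.pi / 2, 721, endpoint=False)
    h, angles, dists = hough_line(mask.astype(np.uint8), theta=theta)
    _, peak_angles, peak_dists = hough_line_peaks(
        h, angles, dists, num_peaks=max_lines,
        threshold=0.4 * float(h.max()),
        min_distance=5, min_angle=5,
    )

    ys, xs = np.nonzero(mask)  # rows = space, cols = time
    cap = kymo.speed_cap_um_s(min_frames)
    out: list[Trajectory] = []
    used: list[tuple[float, float]] = []
    for ang, dist in zip(peak_angles, peak_dists):
        # hough line: x*cos(ang) + y*sin(ang) = dist, with x = col, y = row
        d = np.abs(xs * np.cos(ang) + ys * np.sin(ang) - dist)
        inl = d <= band_px
        if inl.sum() < min_frames:
            continue
        cols = xs[inl]
        rows_sel = ys[inl]
        # one representative spatial position per frame (intensity-weighted)
        frames = np.unique(cols)
        if len(frames) < min_frames:
            continue
        runs = np.split(frames, np.where(np.diff(frames) > 1)[0] + 1)
        longest = max(runs, key=len)
        if len(longest) < min_frames:
            continue
        keep = np.isin(cols, longest)
        cols_k, rows_k = cols[keep], rows_sel[keep]
        w = work[rows_k, cols_k]
        order = np.argsort(cols_k)
        cols_k, rows_k, w = cols_k[order], rows_k[order], w[order]
        uniq, start = np.unique(cols_k, return_index=True)
        centroids = np.array([
            np.average(rows_k[s:e], weights=np.maximum(w[s:e], 1e-6))
            for s, e in zip(start, np.append(start[1:], len(cols_k)))
        ])
        slope_px = theilslopes(centroids, uniq).slope
        v = slope_px * kymo.dx_um / kymo.dt_s
        if abs(v) > cap:
            continue
        # deduplicate: same velocity and overlapping offset
        offset = float(np.median(centroids - slope_px * uniq))
        dup = any(abs(v - pv) < 0.15 * max(abs(v), 1.0) and abs(offset - po) < 6
                  for pv, po in used)
        if dup:
            continue
        used.append((v, offset))
        out.append(Trajectory(velocity_um_s=float(v),
                              t0_s=float(uniq[0] * kymo.dt_s),
                              duration_frames=int(len(longest)),
                              n_points=int(len(uniq))))
    out.sort(key=lambda tr: tr.t0_s)
    return out


def immotile_threshold_um_s(
    temperature_k: float = constants.ROOM_TEMPERATURE_K,
    viscosity_pa_s: float = constants.WATER_VISCOSITY_PA_S,
    radius_m: float = constants.TRACKED_PARTICLE_RADIUS_M,
    dt_video_s: float = 20.0,
) -> float:
    """Average speed of a diffusing particle over the video duration.

    Stokes-Einstein: D = k_B T / (6 pi eta r); v = sqrt(D / dt).  With the
    default constants this evaluates to about 0.6 μm/s; the working
    threshold used for filtering defaults to the slightly more conservative
    0.8 μm/s.
    """
    d_m2_s = constants.BOLTZMANN_J_PER_K * temperature_k / (
        6.0 * np.pi * viscosity_pa_s * radius_m
    )
    return float(np.sqrt(d_m2_s / dt_video_s) * 1e6)


def immotile_filter(trajectories, threshold_um_s: float = constants.IMMOTILE_SPEED_UM_S):
    """Drop trajectories slower than the immotile threshold."""
    return [tr for tr in trajectories if abs(tr.velocity_um_s) >= threshold_um_s]


def velocity_stats(velocities, n_boot: int = 1000, seed: int = 0) -> dict:
    """Direction-partitioned speed statistics of one sample.

    Returns mean tipward <u+>, mean rootward <u->, their absolute ratio
    |<u+>/<u->| (NaN if one-sided), maxima, and bootstrap s.e.m. values.
    """
    v = np.asarray([t.velocity_um_s if isinstance(t, Trajectory) else t
                    for t in velocities], dtype=float)
    up = v[v > 0]
    dn = v[v < 0]
    out = {
        "n_plus": len(up), "n_minus": len(dn),
        "u_plus_mean": float(up.mean()) if len(up) else np.nan,
        "u_minus_mean": float(dn.mean()) if len(dn) else np.nan,
        "u_plus_max": float(up.max()) if len(up) else np.nan,
        "u_minus_max": float(dn.min()) if len(dn) else np.nan,
    }
    if len(up) and len(dn):
        out["ratio"] = abs(out["u_plus_mean"] / out["u_minus_mean"])
    else:
        out["ratio"] = np.nan
        warnings.warn("one-sided sample: tipward/rootward ratio undefined",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    for key, arr in (("u_plus_sem", up), ("u_minus_sem", dn)):
        if len(arr) >= 2:
            means = [rng.choice(arr, len(arr)).mean() for _ in range(n_boot)]
            out[key] = float(np.std(means, ddof=1))
        else:
            out[key] = np.nan
    return out


def diffusion_length_mm(D_um2_s: float, v_g_um_h: float) -> float:
    """Length scale within which diffusion outruns growth: L = 2 D / v_g.

    D in μm^2/s, tip growth speed in μm/h; returns mm.  A stationary tip
    (v_g = 0) gives infinity, flagged by the caller-visible inf value.
    """
    if v_g_um_h == 0:
        warnings.warn("v_g = 0: diffusion length is unbounded", stacklevel=2)
        return float("inf")
    d_um2_h = D_um2_s * 3600.0
    return float(2.0 * d_um2_h / v_g_um_h / 1000.0)


# ---------------------------------------------------------------------------
# mapping onto the network
# ---------------------------------------------------------------------------

def _edge_geometry(graph):
    items = []
    for u, v, data in graph.edges(data=True):
        poly = np.asarray(data["polyline"], dtype=float)
        items.append((u, v, data, poly))
    return items


def _nearest_on_polyline(poly: np.ndarray, p: np.ndarray):
    """(distance, arclength along polyline, index) of the closest point."""
    best = (np.inf, 0.0, 0)
    arc = 0.0
    for i in range(len(poly) - 1):
        a, b = poly[i], poly[i + 1]
        ab = b - a
        L2 = float(ab @ ab)
        if L2 <= 0:
            continue
        t = float(np.clip((p - a) @ ab / L2, 0.0, 1.0))
        q = a + t * ab
        d = float(np.hypot(*(p - q)))
        seg = float(np.sqrt(L2))
        if d < best[0]:
            best = (d, arc + t * seg, i)
        arc += seg
    return best


def _direction_at(poly: np.ndarray, end: str):
    if end == "start":
        d = poly[min(1, len(poly) - 1)] - poly[0]
    else:
        d = poly[-1] - poly[-min(2, len(poly))]
    n = np.hypot(*d)
    return d / n if n > 0 else d


def map_flow_to_network(
    positions_um,
    graph,
    bc_map: dict,
    anchor_nodes=(),
    tolerance_um: float = constants.FLOW_ALIGNMENT_TOLERANCE_UM,
    velocity_sets=None,
) -> list[FlowSample]:
    """Snap video positions onto the network and attach (d_tip, BC).

    Each position is snapped to the nearest edge polyline (within the
    alignment tolerance, else flagged and skipped with a warning).  The
    distance to the tip is the curvilinear length from the snapped point to
    the tip of the *same hypha*, following maximal direction and width
    continuity at junctions; the root-anchor side never counts as a tip.
    """
    geoms = _edge_geometry(graph)
    anchor_set = set(anchor_nodes)
    samples: list[FlowSample] = []
    for si, pos in enumerate(np.atleast_2d(np.asarray(positions_um, dtype=float))):
        best = None
        for u, v, data, poly in geoms:
            d, arc, _ = _nearest_on_polyline(poly, pos)
            if best is None or d < best[0]:
                best = (d, arc, u, v, data, poly)
        if best is None or best[0] > tolerance_um:
            warnings.warn(f"position {pos} farther than {tolerance_um} μm from "
                          "any edge: unmapped", stacklevel=2)
            continue
        d_err, arc, u, v, data, poly = best
        total = float(np.hypot(*np.diff(poly, axis=0).T).sum())

        def walk(node, incoming_dir, width0):
            """Curvilinear length from ``node`` onward along the hypha.

            Returns (length, reached_tip) following direction/width
            continuity; stops at a tip (degree 1, not an anchor) or when no
            continuation exists.
            """
            length = 0.0
            prev = None
            cur = node
            direction = incoming_dir
            for _ in range(10000):
                if graph.degree(cur) == 1:
                    return length, cur not in anchor_set
                nbrs = []
                for _, nb, dd in graph.edges(cur, data=True):
                    if prev is not None and nb == prev:
                        continue
                    pl = np.asarray(dd["polyline"], dtype=float)
                    # orient the polyline leaving cur
                    p0 = np.asarray(graph.nodes[cur]["pos"], dtype=float)
                    if np.hypot(*(pl[0] - p0)) > np.hypot(*(pl[-1] - p0)):
                        pl = pl[::-1]
                    out_dir = _direction_at(pl, "start")
                    cosang = float(direction @ out_dir)
                    dw = abs(float(dd.get("width_um", width0)) - width0)
                    nbrs.append((cosang - 0.05 * dw, nb, dd, pl))
                if not nbrs:
                    return length, False
                score, nb, dd, pl = max(nbrs, key=lambda it: (it[0], str(it[1])))
                if score < 0.5:
                    # no continuation within ~60 degrees: the hypha ends here
                    # (e.g. it terminated by anastomosis, leaving no tip)
                    return length, False
                length += float(np.hypot(*np.diff(pl, axis=0).T).sum())
                direction = _direction_at(pl, "end")
                prev, cur = cur, nb
                deg = graph.degree(cur)
                if deg == 1:
                    return length, cur not in anchor_set
                if deg != 2:
                    # junction: continue, continuity scoring picks the branch
                    continue
            return length, False

        width0 = float(data.get("width_um", 5.0))
        # direction pointing toward node v along the edge
        pv = np.asarray(graph.nodes[v]["pos"], dtype=float)
        if np.hypot(*(poly[-1] - pv)) > np.hypot(*(poly[0] - pv)):
            poly_v = poly[::-1]
            arc_v = arc
        else:
            poly_v = poly
            arc_v = arc
        # try both ends; the side that reaches a non-anchor degree-1 node is
        # the tip side
        dir_to_v = _direction_at(poly_v, "end")
        len_v, tip_v = walk(v, dir_to_v, width0)
        dir_to_u = -_direction_at(poly_v, "start")
        len_u, tip_u = walk(u, dir_to_u, width0)
        to_v = total - arc_v
        to_u = arc_v
        if tip_v and not tip_u:
            d_tip = to_v + len_v
        elif tip_u and not tip_v:
            d_tip = to_u + len_u
        elif tip_v and tip_u:
            d_tip = min(to_v + len_v, to_u + len_u)
        else:
            d_tip = np.nan
        vels = None
        if velocity_sets is not None:
            vels = np.asarray(velocity_sets[si], dtype=float)
        samples.append(FlowSample(
            x_um=float(pos[0]), y_um=float(pos[1]),
            d_tip_mm=float(d_tip) / 1000.0 if np.isfinite(d_tip) else np.nan,
            bc=float(bc_map.get(data["edge_id"], np.nan)),
            velocities_um_s=vels if vels is not None else np.empty(0),
            edge_id=data["edge_id"],
            alignment_error_um=float(d_err),
        ))
    return samples


def flow_gradient_fits(samples: list[FlowSample], covariate: str = "d_tip",
                       n_boot: int = 1000, seed: int = 0) -> dict:
    """Linear fits of <u+> and <u-> against d_tip or BC, with bootstrap CIs.

    Returns, per direction, (slope, intercept, slope 95% CI).
    """
    xs, up, dn = [], [], []
    for s in samples:
        x = s.d_tip_mm if covariate == "d_tip" else s.bc
        if covariate not in ("d_tip", "bc"):
            raise ValueError("covariate must be 'd_tip' or 'bc'")
        v = s.velocities_um_s
        if not np.isfinite(x) or len(v) == 0:
            continue
        vp = v[v > 0]
        vn = v[v < 0]
        xs.append(x)
        up.append(vp.mean() if len(vp) else np.nan)
        dn.append(vn.mean() if len(vn) else np.nan)
    xs = np.asarray(xs)
    up = np.asarray(up)
    dn = np.asarray(dn)
    if len(xs) < 5 or np.ptp(xs[np.isfinite(xs)]) <= 0:
        raise ValueError("need >= 5 samples spanning the covariate")
    rng = np.random.default_rng(seed)
    out = {}
    for name, y in (("u_plus", up), ("u_minus", dn)):
        ok = np.isfinite(y) & np.isfinite(xs)
        if ok.sum() < 3 or np.ptp(xs[ok]) <= 0:
            out[name] = (np.nan, np.nan, (np.nan, np.nan))
            continue
        slope, icpt = np.polyfit(xs[ok], y[ok], 1)
        boots = []
        xo, yo = xs[ok], y[ok]
        for _ in range(n_boot):
            idx = rng.integers(0, len(xo), len(xo))
            if np.ptp(xo[idx]) <= 0:
                continue
            boots.append(np.polyfit(xo[idx], yo[idx], 1)[0])
        ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan,) * 2
        out[name] = (float(slope), float(icpt), ci)
    return out
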