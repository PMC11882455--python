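"""Agent-based generator of synthetic mycorrhizal colonies.

Growing tips advect at a constant per-tip speed with small heading noise,
duplicate by branching at rate alpha, and on contact with an existing
filament either fuse (anastomosis, tip annihilated, three-way junction) or
cross (four-way junction), with one Bernoulli draw per contact.  The output
is a :class:`~mycowave.netmodel.NetworkSeries` plus a ground-truth event
log, which is what the tracking-based detectors in :mod:`mycowave.events`
are validated against.

The generator reproduces the statistical structure of travelling-wave
colony growth: a front advancing at the speed of the fastest tips and a
low, anastomosis-regulated saturation density in the wake.  Branched
absorbing structures (BAS), spores and per-edge flow speeds are decorated
onto the runner-hypha scaffold by separate passes so each can be switched
off independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .netmodel import Junction, NetworkSeries, Trail, snapshot

__all__ = [
    "SimParams",
    "SimReport",
    "simulate_colony",
    "decorate_bas",
    "inject_spores",
    "synthesize_flow_field",
]


@dataclass
class SimParams:
    """Parameters of the tip-growth simulation.

    Defaults follow the measured colony statistics: branching rate
    alpha ~ 0.04 per hour, population mean tip speed ~ 240 μm/h with the
    fastest (front, "puller") tips at ~ 280 μm/h, and a fusion probability
    chosen so the effective annihilation coefficient beta = p_fuse * v *
    <|sin(theta)|> lands near 23 μm/h per unit filament density (the
    realized encounter-angle factor in the partially radially aligned wake
    is <|sin|> ~ 0.26).
    """

    alpha_per_h: float = 0.04
    p_fuse: float = 0.37
    v_mean_um_h: float = 240.0
    v_puller_um_h: float = 280.0
    v_sd_um_h: float = 25.0
    v_min_um_h: float = 200.0
    heading_noise_rad_per_step: float = 0.01
    dt_h: float = 0.25
    t_max_h: float = 100.0
    record_every: int = 4  # output frame every N internal steps
    bas_fraction_target: float = 0.3
    spore_rate_per_mm_h: float = 1.5e-3
    branch_offset_um: float = 0.0  # daughters spawn at the parent apex
    self_exclusion_um: float = 50.0
    #: newborn tips ignore contacts until this far from their origin, so
    #: every branch establishes a track the frame-based detectors can see
    min_establishment_um: float = 150.0
    roi_radius_mm: float = constants.ROI_RADIUS_MM
    roi_offset_mm: float = constants.ROI_BARRIER_OFFSET_MM
    n_anchors: int = 3
    anchor_spread_mm: float = 2.0
    rh_width_mean_um: float = 9.0
    rh_width_sd_um: float = 1.5
    bas_width_mean_um: float = 4.0
    bas_width_sd_um: float = 0.8
    bas_length_range_um: tuple[float, float] = (80.0, 380.0)
    spore_radius_mean_um: float = 40.0
    spore_radius_sd_um: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_per_h", "v_mean_um_h", "v_puller_um_h", "dt_h", "t_max_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_fuse <= 1.0:
            raise ValueError("p_fuse must lie in [0, 1]")
        if not 0.0 <= self.bas_fraction_target < 1.0:
            raise ValueError("bas_fraction_target must lie in [0, 1)")
        self._check_dt()

    def _check_dt(self) -> None:
        """Refuse a timestep so large that tips hop across the mean spacing."""
        if self.p_fuse <= 0 or self.alpha_per_h <= 0:
            return
        beta_est = self.p_fuse * self.v_mean_um_h * 0.26  # <|sin|> of encounters
        rho_sat_est = 2e6 * self.alpha_per_h / beta_est  # μm per mm^2
        spacing_um = 1e6 / rho_sat_est
        step_um = self.v_puller_um_h * self.dt_h
        if step_um > 0.5 * spacing_um:
            suggested = 0.5 * spacing_um / self.v_puller_um_h
            raise ValueError(
                f"dt_h={self.dt_h} is unstable: tips advance {step_um:.0f} μm per "
                f"step but the expected inter-hypha spacing is {spacing_um:.0f} μm; "
                f"use dt_h <= {suggested:.3g}"
            )


@dataclass
class SimReport:
    """Ground-truth tallies and realized statistics of one simulation."""

    n_branchings: int
    n_anastomoses: int
    n_crossings: int
    n_spores: int
    loops_closed: int
    beta_eff_um_per_h: float
    frame_t_h: np.ndarray
    total_length_um: np.ndarray
    n_active_tips: np.ndarray
    tip_speeds_um_h: dict[int, float]
    edge_birth_counts: dict[float, int] = field(default_factory=dict)


class _SimTrail:
    __slots__ = (
        "hid", "verts", "times", "origin_node", "tip_node", "width",
        "heading", "speed", "active", "junction_idx", "junctions",
    )

    def __init__(self, hid, x, y, t, origin_node, tip_node, width, heading, speed):
        self.hid = hid
        self.verts = [(x, y)]
        self.times = [t]
        self.origin_node = origin_node
        self.tip_node = tip_node
        self.width = width
        self.heading = heading
        self.speed = speed
        self.active = True
        self.junction_idx: set[int] = set()
        self.junctions: list[Junction] = []


_CELL_UM = 250.0


def _cells_of_segment(p, q):
    x0, x1 = sorted((p[0], q[0]))
    y0, y1 = sorted((p[1], q[1]))
    for ix in range(int(x0 // _CELL_UM), int(x1 // _CELL_UM) + 1):
        for iy in range(int(y0 // _CELL_UM), int(y1 // _CELL_UM) + 1):
            yield (ix, iy)


def _seg_intersect(p, q, a, b):
    """Parameter s along p->q of the intersection with segment a-b, else None."""
    rx, ry = q[0] - p[0], q[1] - p[1]
    sx, sy = b[0] - a[0], b[1] - a[1]
    denom = rx * sy - ry * sx
    if abs(denom) < 1e-12:
        return None
    qpx, qpy = a[0] - p[0], a[1] - p[1]
    s = (qpx * sy - qpy * sx) / denom
    u = (qpx * ry - qpy * rx) / denom
    if 0.0 < s <= 1.0 and 0.0 <= u <= 1.0:
        return s
    return None


def _draw_speed(rng, params: SimParams) -> float:
    if params.v_sd_um_h <= 0:
        return params.v_mean_um_h
    lo, hi = params.v_min_um_h, params.v_puller_um_h
    for _ in range(64):
        v = rng.normal(params.v_mean_um_h, params.v_sd_um_h)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(rng.normal(params.v_mean_um_h, params.v_sd_um_h), lo, hi))


def simulate_colony(params: SimParams) -> tuple[NetworkSeries, pd.DataFrame, SimReport]:
    """Run the tip-growth simulation; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    roi_r_um = params.roi_radius_mm * 1000.0

    trails: list[_SimTrail] = []
    seg_hash: dict[tuple[int, int], list[tuple[int, int]]] = {}
    next_node = 0
    anchor_nodes: list[int] = []
    anchors: list[tuple[float, float]] = []
    events: list[dict] = []
    # component bookkeeping (union-find over anchor groups) for loop counting
    parent: dict[int, int] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y) -> bool:
        rx, ry = find(x), find(y)
        if rx == ry:
            return False
        parent[rx] = ry
        return True

    trail_comp: dict[int, int] = {}

    for i in range(params.n_anchors):
        if params.n_anchors == 1:
            x = 0.0
        else:
            x = (i / (params.n_anchors - 1) - 0.5) * 2 * params.anchor_spread_mm * 1000.0
        aid = next_node
        next_node += 1
        tid = next_node
        next_node += 1
        anchors.append((x, 0.0))
        anchor_nodes.append(aid)
        width = max(7.5, rng.normal(params.rh_width_mean_um, params.rh_width_sd_um))
        # crossing hyphae fan out into the open compartment
        if params.n_anchors == 1:
            heading = math.pi / 2
        else:
            heading = math.radians(165.0 - 150.0 * i / (params.n_anchors - 1))
        heading += rng.normal(0.0, 0.05)
        tr = _SimTrail(len(trails), x, 0.0, 0.0, aid, tid, width,
                       heading, _draw_speed(rng, params))
        parent[len(parent)] = len(parent)
        trail_comp[tr.hid] = tr.hid
        trails.append(tr)

    # coarse density grid (1 mm cells) for the realized-beta exposure integral
    dens: dict[tuple[int, int], float] = {}
    exposure = 0.0  # sum over tip-steps of local density (μm/mm^2) * dt
    loops_closed = 0
    n_fuse = n_cross = n_branch = 0

    def add_segment(tr: _SimTrail, i0: int) -> None:
        p, q = tr.verts[i0], tr.verts[i0 + 1]
        for c in _cells_of_segment(p, q):
            seg_hash.setdefault(c, []).append((tr.hid, i0))
        mx, my = (p[0] + q[0]) / 2000.0, (p[1] + q[1]) / 2000.0  # mm
        dens_key = (int(mx), int(my))
        dens[dens_key] = dens.get(dens_key, 0.0) + math.hypot(q[0] - p[0], q[1] - p[1])

    n_steps = int(round(params.t_max_h / params.dt_h))
    for step in range(n_steps):
        t_now = step * params.dt_h
        t_next = (step + 1) * params.dt_h
        for tr in list(trails):
            if not tr.active:
                continue
            px, py = tr.verts[-1]
            cell = (int(px // 1000.0), int(py // 1000.0))
            exposure += dens.get(cell, 0.0) * params.dt_h
            tr.heading += rng.normal(0.0, params.heading_noise_rad_per_step)
            step_len = tr.speed * params.dt_h
            qx = px + step_len * math.cos(tr.heading)
            qy = py + step_len * math.sin(tr.heading)
            if math.hypot(qx, qy) > roi_r_um or qy < 0.0:
                # clip the final step to the ROI boundary, then stop
                lo, hi = 0.0, 1.0
                for _ in range(30):
                    mid = 0.5 * (lo + hi)
                    mx, my = px + mid * (qx - px), py + mid * (qy - py)
                    if math.hypot(mx, my) > roi_r_um or my < 0.0:
                        hi = mid
                    else:
                        lo = mid
                if lo > 1e-3:
                    tr.verts.append((px + lo * (qx - px), py + lo * (qy - py)))
                    tr.times.append(t_now + lo * params.dt_h)
                    add_segment(tr, len(tr.verts) - 2)
                tr.active = False
                continue

            # --- contact search (skipped on the final step, where a
            # crossing tip could not lay down its continuation) -------------
            contact = None  # (s, hid2, seg_idx)
            if step == n_steps - 1:
                tr.verts.append((qx, qy))
                tr.times.append(t_next)
                add_segment(tr, len(tr.verts) - 2)
                continue
            seen: set[tuple[int, int]] = set()
            for c in _cells_of_segment((px, py), (qx, qy)):
                for ref in seg_hash.get(c, ()):  # (hid, i0)
                    if ref in seen:
                        continue
                    seen.add(ref)
                    hid2, i0 = ref
                    if hid2 == tr.hid and i0 >= len(tr.verts) - 2 - int(
                        params.self_exclusion_um / max(step_len, 1.0)
                    ):
                        continue
                    other = trails[hid2]
                    s = _seg_intersect((px, py), (qx, qy),
                                       other.verts[i0], other.verts[i0 + 1])
                    if s is None:
                        continue
                    cxp = px + s * (qx - px)
                    cyp = py + s * (qy - py)
                    ox, oy = tr.verts[0]
                    if math.hypot(cxp - ox, cyp - oy) < params.min_establishment_um:
                        continue
                    if contact is None or s < contact[0]:
                        contact = (s, hid2, i0, cxp, cyp)

            handled = False
            if contact is not None:
                s, hid2, i0, cxp, cyp = contact
                host = trails[hid2]
                # snap to the nearest free interior vertex of the host chain
                cand = None
                for j in sorted(range(max(1, i0), min(len(host.verts) - 1, i0 + 2)),
                                key=lambda j: math.hypot(host.verts[j][0] - cxp,
                                                         host.verts[j][1] - cyp)):
                    if j not in host.junction_idx and 0 < j < len(host.verts) - 1:
                        cand = j
                        break
                if cand is not None:
                    hx, hy = host.verts[cand]
                    tau = t_now + s * params.dt_h
                    merged = union(find(trail_comp[tr.hid]), find(trail_comp[host.hid]))
                    if rng.random() < params.p_fuse:
                        tr.verts.append((hx, hy))
                        tr.times.append(tau)
                        add_segment(tr, len(tr.verts) - 2)
                        host.junctions.append(Junction(tr.tip_node, cand, tau))
                        host.junction_idx.add(cand)
                        events.append(dict(event_type="anastomosis", t_h=tau,
                                           x_um=hx, y_um=hy, node_id=tr.tip_node))
                        tr.active = False
                        n_fuse += 1
                        if not merged:
                            loops_closed += 1
                        handled = True
                    else:
                        xid = next_node
                        next_node += 1
                        tr.verts.append((hx, hy))
                        tr.times.append(tau)
                        add_segment(tr, len(tr.verts) - 2)
                        tr.junctions.append(Junction(xid, len(tr.verts) - 1, tau))
                        tr.junction_idx.add(len(tr.verts) - 1)
                        host.junctions.append(Junction(xid, cand, tau))
                        host.junction_idx.add(cand)
                        events.append(dict(event_type="crossing", t_h=tau,
                                           x_um=hx, y_um=hy, node_id=xid))
                        n_cross += 1
                        if not merged:
                            loops_closed += 1
                        handled = True

            if not handled:
                tr.verts.append((qx, qy))
                tr.times.append(t_next)
                add_segment(tr, len(tr.verts) - 2)

                # branching close to the growing apex; daughters are only
                # spawned while at least one output frame remains, so every
                # branch establishes an observable track
                frame_dt = params.dt_h * params.record_every
                if (t_next <= params.t_max_h - frame_dt + 1e-9
                        and rng.random() < params.alpha_per_h * params.dt_h):
                    jid = next_node
                    next_node += 1
                    did = next_node
                    next_node += 1
                    apex_idx = len(tr.verts) - 1
                    tr.junctions.append(Junction(jid, apex_idx, t_next))
                    tr.junction_idx.add(apex_idx)
                    off = rng.uniform(math.radians(30), math.radians(90))
                    if rng.random() < 0.5:
                        off = -off
                    width = max(7.5, rng.normal(params.rh_width_mean_um,
                                                params.rh_width_sd_um))
                    child = _SimTrail(len(trails), qx, qy, t_next, jid, did, width,
                                      tr.heading + off, _draw_speed(rng, params))
                    trail_comp[child.hid] = trail_comp[tr.hid]
                    trails.append(child)
                    events.append(dict(event_type="branching", t_h=t_next,
                                       x_um=qx, y_um=qy, node_id=did))
                    n_branch += 1

    # ---- assemble the series ---------------------------------------------
    frame_dt = params.dt_h * params.record_every
    n_frames = int(round(params.t_max_h / frame_dt)) + 1
    frames = np.arange(n_frames) * frame_dt

    trail_objs = {
        tr.hid: Trail(
            hypha_id=tr.hid,
            verts=np.asarray(tr.verts, dtype=float),
            times=np.asarray(tr.times, dtype=float),
            origin_node=tr.origin_node,
            tip_node=tr.tip_node,
            width_um=tr.width,
            label="RH",
            junctions=tr.junctions,
        )
        for tr in trails
    }

    events_df = pd.DataFrame(
        events, columns=["event_type", "t_h", "x_um", "y_um", "node_id"]
    )
    series = NetworkSeries(
        timepoints=frames,
        node_rows=pd.DataFrame(columns=["node_id", "t_h", "x_um", "y_um", "degree"]),
        trails=trail_objs,
        root_anchors=anchors,
        anchor_nodes=anchor_nodes,
        roi={"offset_mm": params.roi_offset_mm, "radius_mm": params.roi_radius_mm},
        events=events_df,
    )
    total_len, n_tips, edge_counts = _derive_node_rows(series)

    beta_eff = 0.0
    if n_fuse > 0 and exposure > 0:
        beta_eff = n_fuse / (1e-6 * exposure)

    active_speeds = {tr.hid: tr.speed for tr in trails}
    report = SimReport(
        n_branchings=n_branch,
        n_anastomoses=n_fuse,
        n_crossings=n_cross,
        n_spores=0,
        loops_closed=loops_closed,
        beta_eff_um_per_h=beta_eff,
        frame_t_h=frames,
        total_length_um=total_len,
        n_active_tips=n_tips,
        tip_speeds_um_h=active_speeds,
        edge_birth_counts=edge_counts,
    )
    return series, events_df, report


def _derive_node_rows(series: NetworkSeries):
    """Fill ``series.node_rows`` from per-frame snapshots.

    Rows are emitted at a node's first frame and whenever its position or
    degree changes, which is exactly the information a frame-by-frame
    tracker records.  A trail tip's first row uses the trail's birth
    position so that detected branching positions coincide with the
    ground-truth branch point.
    """
    rows: list[tuple] = []
    last: dict[int, tuple] = {}
    tip_of_trail = {tr.tip_node: tr for tr in series.trails.values()}
    total_len = np.zeros(len(series.timepoints))
    n_tips = np.zeros(len(series.timepoints), dtype=int)
    edge_counts: dict[float, int] = {}

    for fi, t in enumerate(series.timepoints):
        g = snapshot(series, t)
        edge_counts[float(t)] = g.number_of_edges()
        total_len[fi] = sum(d["length_um"] for _, _, d in g.edges(data=True))
        for nid in sorted(g.nodes):
            x, y = g.nodes[nid].get("pos", (np.nan, np.nan))
            deg = g.degree(nid)
            if deg == 1 and nid in tip_of_trail:
                tr = tip_of_trail[nid]
                if tr.times[-1] >= t - 1e-9:  # still growing at this frame
                    n_tips[fi] += 1
            state = (round(x, 6), round(y, 6), deg)
            if nid not in last:
                tr = tip_of_trail.get(nid)
                # a growing trail's tip is first recorded at its birth
                # position; trails laid down instantaneously (BAS) are not
                if tr is not None and deg <= 1 and tr.times[-1] > tr.times[0] + 1e-9:
                    state = (round(float(tr.verts[0][0]), 6),
                             round(float(tr.verts[0][1]), 6), 1)
                rows.append((nid, t) + state)
                last[nid] = state
            elif state != last[nid]:
                rows.append((nid, t) + state)
                last[nid] = state
        # tips whose trail exists but has laid no edge yet (zero length so far)
        for tr in series.trails.values():
            nid = tr.tip_node
            if nid in last or tr.times[0] > t:
                continue
            rows.append((nid, t, round(float(tr.verts[0][0]), 6),
                         round(float(tr.verts[0][1]), 6), 1))
            last[nid] = (round(float(tr.verts[0][0]), 6),
                         round(float(tr.verts[0][1]), 6), 1)
    series.node_rows = pd.DataFrame(
        rows, columns=["node_id", "t_h", "x_um", "y_um", "degree"]
    )
    series._rows_by_node = None
    return total_len, n_tips, edge_counts


# ---------------------------------------------------------------------------
# decoration passes
# ---------------------------------------------------------------------------

def decorate_bas(series: NetworkSeries, params: SimParams) -> NetworkSeries:
    """Append short, thin lateral BAS edges behind the advancing front.

    BAS are scheduled frame by frame so the realized length density
    rho_BAS = L_BAS / (L_RH + L_BAS) tracks ``bas_fraction_target``.
    """
    if params.bas_fraction_target >= 1.0:
        raise ValueError("bas_fraction_target must be < 1")
    if params.bas_fraction_target <= 0.0:
        return series
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    target = params.bas_fraction_target

    next_node = int(series.node_rows["node_id"].max()) + 1 if len(series.node_rows) else 0
    for tr in series.trails.values():
        next_node = max(next_node, tr.origin_node + 1, tr.tip_node + 1,
                        *[j.node_id + 1 for j in tr.junctions] or [0])
    next_hid = max(series.trails) + 1

    # work on copies: the input series' trails must stay untouched
    base_trails = {
        hid: Trail(
            hypha_id=tr.hypha_id,
            verts=tr.verts,
            times=tr.times,
            origin_node=tr.origin_node,
            tip_node=tr.tip_node,
            width_um=tr.width_um,
            label=tr.label,
            junctions=list(tr.junctions),
        )
        for hid, tr in series.trails.items()
    }
    rh_trails = [tr for tr in base_trails.values() if tr.label == "RH"]
    new_trails: dict[int, Trail] = {}
    l_bas = 0.0
    lo, hi = params.bas_length_range_um

    for t in series.timepoints:
        l_rh = 0.0
        segs = []  # (trail, cumulative length) of filament existing at t
        for tr in rh_trails:
            k = int(np.searchsorted(tr.times, t + 1e-9)) - 1
            if k < 1:
                continue
            arc = tr.arclengths()[k]
            l_rh += arc
            segs.append((tr, k, arc))
        if l_rh <= 0:
            continue
        need = target / (1.0 - target) * l_rh
        cum = np.cumsum([s[2] for s in segs])
        attempts = 0
        while l_bas + (lo + hi) / 2 < need and attempts < 10000:
            attempts += 1
            u = rng.uniform(0, cum[-1])
            si = int(np.searchsorted(cum, u))
            tr, k, _ = segs[si]
            if k < 2:
                continue
            vi = int(rng.integers(1, k))  # interior vertex index
            occupied = {j.vert_index for j in tr.junctions}
            if vi in occupied:
                continue
            bx, by = tr.verts[vi]
            seg = tr.verts[vi + 1] - tr.verts[vi - 1]
            base = math.atan2(seg[1], seg[0])
            side = 1.0 if rng.random() < 0.5 else -1.0
            ang = base + side * rng.uniform(math.radians(60), math.radians(120))
            length = rng.uniform(lo, hi)
            mx = bx + 0.5 * length * math.cos(ang)
            my = by + 0.5 * length * math.sin(ang)
            ex = bx + length * math.cos(ang)
            ey = by + length * math.sin(ang)
            r_lim = series.roi["radius_mm"] * 1000.0
            if math.hypot(ex, ey) > r_lim or ey < 0:
                continue
            # one bush per attachment: a primary branchlet plus laterals
            # off its midpoint, so RH trails are not shredded into short
            # sub-edges by frequent attachment junctions
            jid, tid = next_node, next_node + 2
            mid_jid = next_node + 1
            next_node += 3
            width = float(np.clip(rng.normal(params.bas_width_mean_um,
                                             params.bas_width_sd_um), 2.0, 6.5))
            primary = Trail(
                hypha_id=next_hid,
                verts=np.array([[bx, by], [mx, my], [ex, ey]]),
                times=np.array([t, t, t]),
                origin_node=jid,
                tip_node=tid,
                width_um=width,
                label="BAS",
            )
            tr.junctions.append(Junction(jid, vi, float(t)))
            new_trails[next_hid] = primary
            next_hid += 1
            l_bas += length
            n_laterals = int(rng.integers(1, 4))
            placed_lateral = False
            for _ in range(n_laterals):
                lat_len = rng.uniform(lo, hi)
                lat_ang = ang + (1 if rng.random() < 0.5 else -1) * rng.uniform(
                    math.radians(30), math.radians(80))
                lx = mx + lat_len * math.cos(lat_ang)
                ly = my + lat_len * math.sin(lat_ang)
                if math.hypot(lx, ly) > r_lim or ly < 0:
                    continue
                lat_tid = next_node
                next_node += 1
                lat_width = float(np.clip(rng.normal(params.bas_width_mean_um,
                                                     params.bas_width_sd_um),
                                          2.0, 6.5))
                new_trails[next_hid] = Trail(
                    hypha_id=next_hid,
                    verts=np.array([[mx, my], [lx, ly]]),
                    times=np.array([t, t]),
                    origin_node=mid_jid,
                    tip_node=lat_tid,
                    width_um=lat_width,
                    label="BAS",
                )
                next_hid += 1
                l_bas += lat_len
                placed_lateral = True
            if placed_lateral:
                primary.junctions.append(Junction(mid_jid, 1, float(t)))

    out = NetworkSeries(
        timepoints=series.timepoints.copy(),
        node_rows=pd.DataFrame(columns=["node_id", "t_h", "x_um", "y_um", "degree"]),
        trails={**base_trails, **new_trails},
        root_anchors=list(series.root_anchors),
        anchor_nodes=list(series.anchor_nodes),
        roi=dict(series.roi),
        pixel_size_um=series.pixel_size_um,
        events=series.events.copy(),
        spores=series.spores.copy(),
    )
    _derive_node_rows(out)
    return out


def inject_spores(series: NetworkSeries, params: SimParams) -> pd.DataFrame:
    """Place spores on filaments at a rate proportional to local length.

    The per-frame spore count is Poisson with mean
    ``rate * total_length_mm * frame_interval``; spores are positioned
    uniformly along the filament existing at that frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 202]))
    rate = params.spore_rate_per_mm_h
    rows: list[dict] = []
    sid = 0
    tps = series.timepoints
    for fi in range(1, len(tps)):
        t = tps[fi]
        dt = t - tps[fi - 1]
        segs, cum = [], []
        total = 0.0
        for tr in series.trails.values():
            k = int(np.searchsorted(tr.times, t + 1e-9)) - 1
            if k < 1:
                continue
            arc = float(tr.arclengths()[k])
            total += arc
            segs.append((tr, k))
            cum.append(total)
        if total <= 0:
            continue
        n_new = rng.poisson(rate * (total / 1000.0) * dt)
        for _ in range(n_new):
            u = rng.uniform(0, total)
            si = int(np.searchsorted(cum, u))
            tr, k = segs[si]
            arcs = tr.arclengths()
            pos = rng.uniform(0, arcs[k])
            vi = int(np.searchsorted(arcs, pos))
            vi = min(max(vi, 1), k)
            frac = (pos - arcs[vi - 1]) / max(arcs[vi] - arcs[vi - 1], 1e-9)
            p = tr.verts[vi - 1] + frac * (tr.verts[vi] - tr.verts[vi - 1])
            radius = float(np.clip(rng.normal(params.spore_radius_mean_um,
                                              params.spore_radius_sd_um), 15.0, 80.0))
            rows.append(dict(spore_id=sid, t_h=float(t), x_um=float(p[0]),
                             y_um=float(p[1]), radius_um=radius))
            sid += 1
    spores = pd.DataFrame(rows, columns=["spore_id", "t_h", "x_um", "y_um", "radius_um"])
    series.spores = spores
    return spores


def synthesize_flow_field(
    series: NetworkSeries,
    t: float,
    bc_map: dict,
    k1_um_s: float = 10.0,
    k2_um_s_per_mm: float = 0.3,
    cap_um_s: float = 12.0,
    tipward_bias: float = 1.0,
) -> dict:
    """Assign ground-truth mean signed flow speeds to each snapshot edge.

    The default rule couples speed magnitude to network position:
    ``|u| = k1 * (BC - 1)/N + k2 * d_tip``, capped, where ``(BC - 1)/N`` is
    the edge's excess betweenness per network node (zero for tip edges) and
    ``d_tip`` is the curvilinear distance from the edge midpoint to the tip
    of its own hypha.  Returns ``{edge_id: (u_tipward, u_rootward)}`` with
    tipward positive and rootward negative.
    """
    if bc_map is None:
        raise ValueError("betweenness map is required (compute it first)")
    g = snapshot(series, t)
    n_nodes = max(g.number_of_nodes(), 1)
    field_out: dict = {}
    for u, v, data in g.edges(data=True):
        if data["label"] != "RH":
            continue
        eid = data["edge_id"]
        if eid not in bc_map:
            raise ValueError(f"edge {eid} missing from the betweenness map")
        tr = series.trails[data["hypha_id"]]
        k = int(np.searchsorted(tr.times, t + 1e-9)) - 1
        arcs = tr.arclengths()
        # arclength of the edge's tipward end along its trail, so that the
        # edge carrying the growing tip gets d_tip = 0 exactly
        poly = data["polyline"]
        d = np.hypot(*np.diff(poly, axis=0).T)
        start = poly[0]
        idx = int(np.argmin(np.hypot(tr.verts[:, 0] - start[0],
                                     tr.verts[:, 1] - start[1])))
        end_arc = arcs[idx] + d.sum()
        d_tip_mm = max(arcs[k] - end_arc, 0.0) / 1000.0
        mag = min(cap_um_s,
                  k1_um_s * max(bc_map[eid] - 1.0, 0.0) / n_nodes
                  + k2_um_s_per_mm * d_tip_mm)
        field_out[eid] = (tipward_bias * mag, -mag)
    return field_out
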