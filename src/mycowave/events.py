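"""Tracking-based classification and event detection on network series.

Implements the tracker-style definitions used on the imaging data:

* growing tips are degree-1 nodes displaced by at least 40 px between the
  frames where they are detected;
* an anastomosis is a tracked node whose degree jumps from 1 to 3 and never
  reverts to 1; nodes whose degree does revert are crossings;
* a branching is a growing tip appearing for the first time after the
  initial frame;
* edges are branched absorbing structures (BAS) if they are short, short
  with a tip end, or thin with a small width*length product; growing tips
  are runner-hypha (RH) tips if their net displacement exceeds 2.5 mm;
* ring-binned branching and anastomosis rates yield the linear scaling
  coefficients alpha (branching per tip) and beta (annihilation per tip per
  unit filament density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .netmodel import NetworkSeries, euler_loop_count, snapshot
from .waveprofile import DensityProfiles, RingFrame

__all__ = [
    "classify_edges_bas_rh",
    "growing_tips",
    "classify_tips_rh_bas",
    "detect_anastomoses",
    "detect_branchings",
    "detect_crossings_from_history",
    "ring_event_rates",
    "estimate_alpha_beta",
    "anastomosis_density",
    "RateProfiles",
]


# ---------------------------------------------------------------------------
# edge and tip classification
# ---------------------------------------------------------------------------

def classify_edges_bas_rh(graph) -> dict:
    """Label every snapshot edge BAS or RH with the triggering criterion.

    Criteria (any one suffices for BAS): (1) length < 400 μm; (2) length
    < 1,000 μm with a degree-1 endpoint; (3) mean width < 7 μm and
    width*length < 9,000 μm^2.  Returns
    ``{edge_id: {"label": ..., "criterion": 0|1|2|3}}`` where criterion 0
    means no criterion fired (an RH edge).
    """
    out = {}
    for u, v, data in graph.edges(data=True):
        length = float(data["length_um"])
        width = data.get("width_um")
        crit = 0
        if length < constants.BAS_MAX_LENGTH_UM:
            crit = 1
        elif length < constants.BAS_TIP_MAX_LENGTH_UM and (
            graph.degree(u) == 1 or graph.degree(v) == 1
        ):
            crit = 2
        elif width is not None and not np.isnan(width):
            if (width < constants.BAS_MAX_WIDTH_UM
                    and width * length < constants.BAS_MAX_WIDTH_LENGTH_UM2):
                crit = 3
        elif width is None or np.isnan(width):
            import warnings

            warnings.warn(
                f"edge {data.get('edge_id')}: missing width, criterion 3 skipped",
                stacklevel=2,
            )
        out[data["edge_id"]] = {
            "label": "BAS" if crit else "RH",
            "criterion": crit,
        }
    return out


def bas_length_density(graph, classes: dict | None = None):
    """(L_RH, L_BAS, rho_BAS) with rho_BAS = L_BAS / (L_RH + L_BAS)."""
    classes = classes or classify_edges_bas_rh(graph)
    l_rh = l_bas = 0.0
    for _, _, data in graph.edges(data=True):
        if classes[data["edge_id"]]["label"] == "BAS":
            l_bas += data["length_um"]
        else:
            l_rh += data["length_um"]
    total = l_rh + l_bas
    return l_rh, l_bas, (l_bas / total if total > 0 else np.nan)


def _node_histories(series: NetworkSeries) -> dict[int, np.ndarray]:
    """node_id -> array of (t, x, y, degree) rows, time ordered."""
    df = series.node_rows.sort_values(["node_id", "t_h"])
    return {
        int(nid): g[["t_h", "x_um", "y_um", "degree"]].to_numpy()
        for nid, g in df.groupby("node_id")
    }


def growing_tips(series: NetworkSeries,
                 min_displacement_px: float = constants.GROWING_TIP_MIN_DISPLACEMENT_PX
                 ) -> dict[float, list[int]]:
    """Growing tips per timepoint.

    A degree-1 node counts as growing at frame t if it moved at least
    ``min_displacement_px * pixel_size_um`` since the previous frame where
    it was recorded (a newborn node qualifies retroactively through its
    first displacement, so a tip's first frame is not silently dropped).
    """
    thr = min_displacement_px * series.pixel_size_um
    hist = _node_histories(series)
    out: dict[float, list[int]] = {float(t): [] for t in series.timepoints}
    for nid, rows in hist.items():
        for i in range(len(rows)):
            t, x, y, deg = rows[i]
            if deg != 1:
                continue
            if i > 0:
                disp = np.hypot(x - rows[i - 1][1], y - rows[i - 1][2])
                if disp >= thr:
                    out[float(t)].append(nid)
            else:
                # first detection: growing if it moves away by the next row
                if (len(rows) > 1
                        and np.hypot(rows[1][1] - x, rows[1][2] - y) >= thr):
                    out[float(t)].append(nid)
    for t in out:
        out[t].sort()
    return out


def classify_tips_rh_bas(series: NetworkSeries,
                         growing: dict[float, list[int]] | None = None,
                         threshold_um: float = constants.RH_TIP_NET_DISPLACEMENT_UM
                         ) -> dict[int, str]:
    """Label growing tips RH or BAS by net displacement from first position."""
    growing = growing if growing is not None else growing_tips(series)
    ids = sorted({nid for tips in growing.values() for nid in tips})
    hist = _node_histories(series)
    labels = {}
    for nid in ids:
        rows = hist[nid]
        net = np.hypot(rows[-1][1] - rows[0][1], rows[-1][2] - rows[0][2])
        labels[nid] = "RH" if net > threshold_um else "BAS"
    return labels


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_anastomoses(series: NetworkSeries) -> pd.DataFrame:
    """Anastomosis events: tracked nodes whose degree jumps 1 -> 3 for good.

    Event position is the three-way junction (the node's position once at
    degree 3); event time is the last frame at which the node was degree 1.
    """
    hist = _node_histories(series)
    rows = []
    for nid, h in hist.items():
        degs = h[:, 3].astype(int)
        hit = None
        for i in range(1, len(degs)):
            if degs[i - 1] == 1 and degs[i] == 3:
                if np.all(degs[i:] != 1):
                    hit = i
                break  # only the first 1->3 transition can qualify
        if hit is not None:
            rows.append(dict(event_type="anastomosis", t_h=float(h[hit - 1][0]),
                             x_um=float(h[hit][1]), y_um=float(h[hit][2]),
                             node_id=nid))
    df = pd.DataFrame(rows, columns=["event_type", "t_h", "x_um", "y_um", "node_id"])
    return df.sort_values(["t_h", "node_id"]).reset_index(drop=True)


def detect_crossings_from_history(series: NetworkSeries) -> pd.DataFrame:
    """Crossings by the tracker rule: degree 1 -> 3 that reverts to 1."""
    hist = _node_histories(series)
    rows = []
    for nid, h in hist.items():
        degs = h[:, 3].astype(int)
        for i in range(1, len(degs)):
            if degs[i - 1] == 1 and degs[i] == 3 and np.any(degs[i:] == 1):
                rows.append(dict(event_type="crossing", t_h=float(h[i][0]),
                                 x_um=float(h[i][1]), y_um=float(h[i][2]),
                                 node_id=nid))
                break
    return pd.DataFrame(rows, columns=["event_type", "t_h", "x_um", "y_um", "node_id"])


def detect_branchings(series: NetworkSeries,
                      growing: dict[float, list[int]] | None = None) -> pd.DataFrame:
    """Branching events: growing tips appearing after the first frame.

    The event is stamped at the node's first recorded frame with its first
    recorded (birth) position; tips already present at the initial
    timepoint are pre-existing, not branchings.
    """
    growing = growing if growing is not None else growing_tips(series)
    ever_growing = {nid for tips in growing.values() for nid in tips}
    hist = _node_histories(series)
    t0 = float(series.timepoints[0])
    rows = []
    for nid in sorted(ever_growing):
        h = hist[nid]
        if float(h[0][0]) <= t0 + 1e-9:
            continue
        rows.append(dict(event_type="branching", t_h=float(h[0][0]),
                         x_um=float(h[0][1]), y_um=float(h[0][2]), node_id=nid))
    df = pd.DataFrame(rows, columns=["event_type", "t_h", "x_um", "y_um", "node_id"])
    return df.sort_values(["t_h", "node_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# rates and scaling coefficients
# ---------------------------------------------------------------------------

@dataclass
class RateProfiles:
    rings: RingFrame
    t_h: np.ndarray  # interval start times, (n_t - 1,)
    branching: np.ndarray  # (n_t - 1, n_rings), mm^-2 h^-1
    anastomosis: np.ndarray


def ring_event_rates(branchings: pd.DataFrame, anastomoses: pd.DataFrame,
                     rings: RingFrame, timepoints) -> RateProfiles:
    """Events per ring area per unit time on the frame intervals.

    An event in ring k during [t_i, t_{i+1}) contributes
    ``1 / (ring area * interval)`` to the corresponding bin.
    """
    t = np.asarray(timepoints, dtype=float)
    nt = len(t) - 1
    b = np.zeros((nt, rings.n_rings))
    a = np.zeros((nt, rings.n_rings))
    for df, arr in ((branchings, b), (anastomoses, a)):
        if df is None or df.empty:
            continue
        r = np.hypot(df["x_um"].to_numpy() - rings.origin[0],
                     df["y_um"].to_numpy() - rings.origin[1]) / 1000.0
        k = np.searchsorted(rings.boundaries_mm, r, side="right") - 1
        ti = np.searchsorted(t, df["t_h"].to_numpy(), side="right") - 1
        ti = np.clip(ti, 0, nt - 1)
        ok = (k >= 0) & (k < rings.n_rings)
        for kk, ii in zip(k[ok], ti[ok]):
            arr[ii, kk] += 1.0
    dt = np.diff(t)[:, None]
    b /= rings.area_mm2 * dt
    a /= rings.area_mm2 * dt
    return RateProfiles(rings=rings, t_h=t[:-1], branching=b, anastomosis=a)


def estimate_alpha_beta(rates: RateProfiles, profiles: DensityProfiles,
                        n_boot: int = 1000, seed: int = 0):
    """Recover alpha and beta by zero-intercept regression in the ring frame.

    alpha is the slope of the branching rate b on the tip density n;
    beta the slope of the anastomosis rate a on the product n * rho
    (with rho converted so that beta carries units μm/h).  Confidence
    intervals come from bootstrap over rings.
    Returns ((alpha, alpha_CI), (beta, beta_CI)).
    """
    # align: rates live on intervals [t_i, t_{i+1}); use densities at t_i
    nt = len(rates.t_h)
    n = profiles.n_tips[:nt]
    rho = profiles.rho[:nt]
    b = rates.branching
    a = rates.anastomosis
    nrho = n * rho * 1e-6  # tip density times filament density in μm^-1

    def slope0(x, y):
        xx = float(np.sum(x * x))
        if xx <= 0:
            raise ValueError("degenerate regressor (no variance)")
        return float(np.sum(x * y) / xx)

    alpha = slope0(n.ravel(), b.ravel())
    beta = slope0(nrho.ravel(), a.ravel())

    rng = np.random.default_rng(seed)
    n_rings = rates.rings.n_rings
    boots_a, boots_b = [], []
    for _ in range(n_boot):
        ks = rng.integers(0, n_rings, n_rings)
        try:
            boots_a.append(slope0(n[:, ks].ravel(), b[:, ks].ravel()))
            boots_b.append(slope0(nrho[:, ks].ravel(), a[:, ks].ravel()))
        except ValueError:
            continue
    ci_a = tuple(np.percentile(boots_a, [2.5, 97.5])) if boots_a else (np.nan,) * 2
    ci_b = tuple(np.percentile(boots_b, [2.5, 97.5])) if boots_b else (np.nan,) * 2
    return (alpha, ci_a), (beta, ci_b)


def anastomosis_density(series: NetworkSeries, per: str = "length"):
    """Cumulative loop count and loop density over time.

    The cumulative anastomosis count is the Euler loop count (e - v + c) of
    each snapshot, which includes fusions at crossing points.  The density
    rho_A divides by total network length (loops per mm; ``per='length'``)
    or by the region area (``per='area'``).
    Returns (t, cumulative counts, rho_A).
    """
    t = series.timepoints
    counts = np.zeros(len(t), dtype=int)
    rho_a = np.full(len(t), np.nan)
    for i, tt in enumerate(t):
        g = snapshot(series, tt)
        counts[i] = euler_loop_count(g) if g.number_of_nodes() else 0
        if per == "length":
            total_mm = sum(d["length_um"] for *_, d in g.edges(data=True)) / 1000.0
            if total_mm > 0:
                rho_a[i] = counts[i] / total_mm
        elif per == "area":
            area = np.pi / 2.0 * series.roi["radius_mm"] ** 2
            rho_a[i] = counts[i] / area
        else:
            raise ValueError("per must be 'length' or 'area'")
    return t, counts, rho_a
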