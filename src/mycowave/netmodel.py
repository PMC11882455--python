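"""Data model and I/O for time-resolved spatial hyphal network graphs.

A colony is represented as a set of *trails*: the polyline trace left by a
single growing tip, with a lay-down time per vertex.  Junctions (branch
points, anastomoses, crossings, lateral attachment points) subdivide trails
into edges.  Because a junction can form on a trail long after the trail was
laid (a later tip fuses with or crosses an old hypha), the serialized edge
table stores the *final* junction-to-junction decomposition together with
the time at which each subdivision became real.  ``snapshot`` reconstructs
the instantaneous graph at any recorded timepoint by truncating trails at
the lay-down time and merging sub-edges across junctions that do not yet
exist; the merged edge is reported under the id of its earliest sub-edge,
so element-id sets only ever grow over time.

This mirrors what frame-by-frame skeleton extraction plus node tracking
produces on real image series: earlier frames show an unbroken hypha, and
when a tip annihilates on it the new three-way junction inherits the
tracked identity of the annihilated tip (its degree history reads 1 -> 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import LineString

from . import constants

__all__ = [
    "Junction",
    "Trail",
    "NetworkSeries",
    "SeriesParseError",
    "snapshot",
    "euler_loop_count",
    "save_series",
    "load_series",
    "export_graphml",
]


class SeriesParseError(ValueError):
    """Structured parse/validation error naming the offending file and row."""

    def __init__(self, message: str, file: str | None = None, row: int | None = None):
        self.file = file
        self.row = row
        where = ""
        if file is not None:
            where = f" [{file}" + (f", row {row}]" if row is not None else "]")
        super().__init__(message + where)


@dataclass
class Junction:
    """An interior subdivision point of a trail.

    ``vert_index`` points at the shared vertex of the trail polyline;
    ``t_h`` is the time at which the junction became topologically real
    (branching / fusion / crossing time), which can be much later than the
    lay-down time of the vertex it sits on.
    """

    node_id: int
    vert_index: int
    t_h: float


@dataclass
class Trail:
    """The polyline trace of one hypha (one growing tip)."""

    hypha_id: int
    verts: np.ndarray  # (k, 2) positions, μm
    times: np.ndarray  # (k,) lay-down time per vertex, hours, non-decreasing
    origin_node: int
    tip_node: int
    width_um: float
    label: str = "RH"  # ground-truth label: RH | BAS
    junctions: list[Junction] = field(default_factory=list)

    def birth_t(self) -> float:
        return float(self.times[0])

    def arclengths(self) -> np.ndarray:
        d = np.diff(self.verts, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])

    def boundaries(self) -> list[Junction]:
        """Origin + interior junctions + tip, ordered along the trail."""
        interior = sorted(self.junctions, key=lambda j: (j.vert_index, j.t_h))
        first = Junction(self.origin_node, 0, self.birth_t())
        last = Junction(self.tip_node, len(self.verts) - 1, self.birth_t())
        return [first] + interior + [last]


@dataclass
class NetworkSeries:
    """Time-resolved spatial network graph with persistent identities."""

    timepoints: np.ndarray  # hours, strictly increasing
    node_rows: pd.DataFrame  # node_id, t_h, x_um, y_um, degree
    trails: dict[int, Trail]
    root_anchors: list[tuple[float, float]]
    anchor_nodes: list[int]
    roi: dict  # {"offset_mm": float, "radius_mm": float}
    pixel_size_um: float = constants.PIXEL_SIZE_UM
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["event_type", "t_h", "x_um", "y_um", "node_id"]
        )
    )
    spores: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["spore_id", "t_h", "x_um", "y_um", "radius_um"]
        )
    )

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(self.timepoints) > 1 and not np.all(np.diff(self.timepoints) > 0):
            raise SeriesParseError("timepoints are not strictly increasing")
        self._rows_by_node = None

    # -- node queries -------------------------------------------------------
    def _node_groups(self):
        if self._rows_by_node is None:
            df = self.node_rows.sort_values(["node_id", "t_h"])
            self._rows_by_node = {
                nid: g[["t_h", "x_um", "y_um", "degree"]].to_numpy()
                for nid, g in df.groupby("node_id")
            }
        return self._rows_by_node

    def node_state(self, node_id: int, t: float):
        """(x, y, degree) from the last recorded row at or before ``t``.

        Returns ``None`` if the node has not appeared yet.
        """
        rows = self._node_groups().get(node_id)
        if rows is None:
            return None
        idx = np.searchsorted(rows[:, 0], t + 1e-9) - 1
        if idx < 0:
            return None
        return rows[idx, 1], rows[idx, 2], int(rows[idx, 3])

    def node_ids(self) -> np.ndarray:
        return np.sort(self.node_rows["node_id"].unique())

    # -- validation ---------------------------------------------------------
    def validate(self, check_degrees: bool = True) -> None:
        known = set(self.node_rows["node_id"].astype(int))
        for hid, tr in self.trails.items():
            if len(tr.verts) != len(tr.times):
                raise SeriesParseError(f"hypha {hid}: vertex/time length mismatch")
            if np.any(np.diff(tr.times) < -1e-9):
                raise SeriesParseError(f"hypha {hid}: vertex times decrease")
            for b in tr.boundaries():
                if b.node_id not in known:
                    raise SeriesParseError(
                        f"hypha {hid} references unknown node {b.node_id}",
                        file="edges.csv",
                    )
        r_max_um = self.roi["radius_mm"] * 1000.0
        xs = self.node_rows["x_um"].to_numpy()
        ys = self.node_rows["y_um"].to_numpy()
        if np.any(np.hypot(xs, ys) > r_max_um * 1.001) or np.any(ys < -1e-6):
            bad = int(np.argmax(np.hypot(xs, ys) > r_max_um * 1.001))
            raise SeriesParseError(
                "node position outside the region of interest",
                file="nodes.csv",
                row=bad,
            )
        if check_degrees:
            for t in self.timepoints:
                g = snapshot(self, t)
                for nid in g.nodes:
                    st = self.node_state(nid, t)
                    if st is not None and g.degree(nid) != st[2]:
                        raise SeriesParseError(
                            f"degree mismatch for node {nid} at t={t}: "
                            f"graph {g.degree(nid)} vs stored {st[2]}"
                        )


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def _truncate_index(times: np.ndarray, t: float) -> int:
    """Index of the last vertex laid down at or before ``t`` (-1 if none)."""
    return int(np.searchsorted(times, t + 1e-9)) - 1


def snapshot(series: NetworkSeries, t: float) -> nx.MultiGraph:
    """Static graph of all elements present at recorded timepoint ``t``.

    Edge attributes: ``edge_id`` (stable ``(hypha_id, seq)`` of the earliest
    constituent sub-edge), ``length_um``, ``width_um``, ``label``,
    ``polyline`` (truncated vertex array), ``hypha_id``, ``birth_t_h``.
    """
    tps = series.timepoints
    if not np.any(np.isclose(tps, t)):
        raise ValueError(
            f"t={t} is not a recorded timepoint; available: {np.round(tps, 3).tolist()}"
        )
    g = nx.MultiGraph()
    for tr in series.trails.values():
        k = _truncate_index(tr.times, t)
        if k < 0:
            continue
        bounds = tr.boundaries()
        # Active boundaries: the origin, every interior junction already
        # formed and already laid down, and the moving tip at the
        # truncation vertex.
        active: list[tuple[int, int]] = [(bounds[0].node_id, 0)]
        for j in bounds[1:-1]:
            # a junction is real only once it is strictly interior to the
            # laid-down chain; at the very frame it coincides with the
            # truncation end the moving tip is still the chain's endpoint
            if j.t_h <= t + 1e-9 and j.vert_index < k:
                active.append((j.node_id, j.vert_index))
        active.append((tr.tip_node, k))
        arcs = tr.arclengths()
        # Sequence numbers follow the *final* decomposition so ids are stable.
        seq_of_index = {b.vert_index: s for s, b in enumerate(bounds[:-1])}
        for (u, iu), (v, iv) in zip(active[:-1], active[1:]):
            if iu >= iv and not (iu == iv == 0):
                continue
            seq = seq_of_index.get(iu, 0)
            poly = tr.verts[iu : iv + 1]
            length = float(arcs[iv] - arcs[iu])
            if length <= 0:
                continue
            g.add_edge(
                u,
                v,
                key=(tr.hypha_id, seq),
                edge_id=(tr.hypha_id, seq),
                length_um=length,
                width_um=tr.width_um,
                label=tr.label,
                polyline=poly,
                hypha_id=tr.hypha_id,
                birth_t_h=float(tr.times[iu]),
            )
            for nid, idx in ((u, iu), (v, iv)):
                g.nodes[nid]["pos"] = (float(tr.verts[idx, 0]), float(tr.verts[idx, 1]))
    # isolated anchors (e.g. before any growth) keep their positions
    for nid, (x, y) in zip(series.anchor_nodes, series.root_anchors):
        if nid not in g:
            g.add_node(nid, pos=(float(x), float(y)))
    return g


def euler_loop_count(graph: nx.Graph) -> int:
    """Number of independent loops, ``e - v + c`` (the planar face count).

    For a planar-embedded growth-only network every independent cycle was
    closed by a hyphal fusion or loop-closing crossing, so this equals the
    cumulative anastomosis count in the graph-theoretic sense.
    """
    v = graph.number_of_nodes()
    e = graph.number_of_edges()
    if v == 0:
        import warnings

        warnings.warn("euler_loop_count called on an empty graph", stacklevel=2)
        return 0
    c = nx.number_connected_components(graph)
    return e - v + c


# ---------------------------------------------------------------------------
# serialization: CSV bundle
# ---------------------------------------------------------------------------

_NODE_COLS = ["node_id", "t_h", "x_um", "y_um", "degree"]
_EDGE_COLS = [
    "edge_id",
    "node_a",
    "node_b",
    "birth_t_h",
    "length_um",
    "width_um",
    "label",
    "polyline_wkt",
    "hypha_id",
    "seq",
    "split_t_h",
    "vertex_t_h",
]
_EVENT_COLS = ["event_type", "t_h", "x_um", "y_um", "node_id"]
_SPORE_COLS = ["spore_id", "t_h", "x_um", "y_um", "radius_um"]


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def save_series(series: NetworkSeries, path: str | Path) -> Path:
    """Write a series bundle: nodes/edges/events/spores CSVs + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nodes = series.node_rows[_NODE_COLS].copy()
    nodes = nodes.sort_values(["t_h", "node_id"]).reset_index(drop=True)
    nodes.to_csv(path / "nodes.csv", index=False, float_format="%.10g")

    rows = []
    next_id = 0
    for hid in sorted(series.trails):
        tr = series.trails[hid]
        bounds = tr.boundaries()
        arcs = tr.arclengths()
        for seq, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            ia, ib = a.vert_index, b.vert_index
            if ib <= ia:
                continue
            poly = tr.verts[ia : ib + 1]
            rows.append(
                {
                    "edge_id": next_id,
                    "node_a": a.node_id,
                    "node_b": b.node_id,
                    "birth_t_h": _fmt(tr.times[ia]),
                    "length_um": _fmt(arcs[ib] - arcs[ia]),
                    "width_um": _fmt(tr.width_um),
                    "label": tr.label,
                    "polyline_wkt": LineString(poly).wkt,
                    "hypha_id": hid,
                    "seq": seq,
                    "split_t_h": _fmt(a.t_h if seq > 0 else tr.times[0]),
                    "vertex_t_h": ";".join(_fmt(v) for v in tr.times[ia : ib + 1]),
                }
            )
            next_id += 1
    pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path / "edges.csv", index=False)

    series.events[_EVENT_COLS].to_csv(
        path / "events.csv", index=False, float_format="%.10g"
    )
    series.spores[_SPORE_COLS].to_csv(
        path / "spores.csv", index=False, float_format="%.10g"
    )
    meta = {
        "roi": series.roi,
        "pixel_size_um": series.pixel_size_um,
        "root_anchors": [list(a) for a in series.root_anchors],
        "anchor_nodes": [int(n) for n in series.anchor_nodes],
        "timepoints": [float(t) for t in series.timepoints],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SeriesParseError(f"missing column(s) {missing}", file=fname)


def load_series(path: str | Path, check_degrees: bool = False) -> NetworkSeries:
    """Load and validate a series bundle written by :func:`save_series`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    nodes = pd.read_csv(path / "nodes.csv")
    _require_columns(nodes, _NODE_COLS, "nodes.csv")
    edges = pd.read_csv(path / "edges.csv")
    _require_columns(edges, _EDGE_COLS, "edges.csv")
    events = pd.read_csv(path / "events.csv") if (path / "events.csv").exists() else None
    spores = pd.read_csv(path / "spores.csv") if (path / "spores.csv").exists() else None

    tps = np.asarray(meta["timepoints"], dtype=float)
    if len(tps) > 1 and not np.all(np.diff(tps) > 0):
        raise SeriesParseError("non-increasing timepoints", file="meta.json")

    known_nodes = set(nodes["node_id"].astype(int))
    trails: dict[int, Trail] = {}
    for hid, grp in edges.groupby("hypha_id"):
        grp = grp.sort_values("seq")
        verts_parts: list[np.ndarray] = []
        times_parts: list[np.ndarray] = []
        junctions: list[Junction] = []
        origin = int(grp.iloc[0]["node_a"])
        tip = int(grp.iloc[-1]["node_b"])
        offset = 0
        for _, row in grp.iterrows():
            for col, nid in (("node_a", row["node_a"]), ("node_b", row["node_b"])):
                if int(nid) not in known_nodes:
                    raise SeriesParseError(
                        f"edge {int(row['edge_id'])} references unknown node {int(nid)}",
                        file="edges.csv",
                        row=int(row.name),
                    )
            geom = shapely_wkt.loads(row["polyline_wkt"])
            pv = np.asarray(geom.coords, dtype=float)
            tv = np.asarray([float(s) for s in str(row["vertex_t_h"]).split(";")])
            if len(pv) != len(tv):
                raise SeriesParseError(
                    "polyline/vertex-time length mismatch",
                    file="edges.csv",
                    row=int(row.name),
                )
            seg = np.hypot(*np.diff(pv, axis=0).T).sum()
            if seg + 1e-6 < np.hypot(*(pv[-1] - pv[0])):
                raise SeriesParseError(
                    "edge length below endpoint distance",
                    file="edges.csv",
                    row=int(row.name),
                )
            if int(row["seq"]) > 0:
                junctions.append(
                    Junction(int(row["node_a"]), offset, float(row["split_t_h"]))
                )
                verts_parts.append(pv[1:])
                times_parts.append(tv[1:])
                offset += len(pv) - 1
            else:
                verts_parts.append(pv)
                times_parts.append(tv)
                offset += len(pv) - 1
        width = float(grp.iloc[0]["width_um"])
        label = str(grp.iloc[0]["label"])
        trails[int(hid)] = Trail(
            hypha_id=int(hid),
            verts=np.vstack(verts_parts),
            times=np.concatenate(times_parts),
            origin_node=origin,
            tip_node=tip,
            width_um=width,
            label=label,
            junctions=junctions,
        )

    series = NetworkSeries(
        timepoints=tps,
        node_rows=nodes,
        trails=trails,
        root_anchors=[tuple(a) for a in meta["root_anchors"]],
        anchor_nodes=[int(n) for n in meta["anchor_nodes"]],
        roi=meta["roi"],
        pixel_size_um=float(meta["pixel_size_um"]),
        events=events if events is not None else pd.DataFrame(columns=_EVENT_COLS),
        spores=spores if spores is not None else pd.DataFrame(columns=_SPORE_COLS),
    )
    series.validate(check_degrees=check_degrees)
    return series


def export_graphml(series: NetworkSeries, t: float, path: str | Path,
                   bc: dict | None = None) -> Path:
    """Write one snapshot as GraphML (positions, lengths, widths, labels)."""
    g = snapshot(series, t)
    out = nx.Graph()
    for nid, data in g.nodes(data=True):
        x, y = data.get("pos", (np.nan, np.nan))
        out.add_node(nid, x=float(x), y=float(y))
    for u, v, data in g.edges(data=True):
        attrs = {
            "length_um": float(data["length_um"]),
            "width_um": float(data["width_um"]),
            "label": str(data["label"]),
        }
        if bc is not None:
            attrs["bc"] = float(bc.get(data["edge_id"], 0.0))
        out.add_edge(u, v, **attrs)
    path = Path(path)
    nx.write_graphml(out, path)
    return path
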