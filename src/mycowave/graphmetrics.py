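"""Root-anchored betweenness, transport efficiencies and reference networks.

Betweenness centrality here counts, for every network node, one
length-weighted shortest path to the nearest root-compartment anchor; an
edge's BC is the number of such paths traversing it.  Geometric transport
efficiency compares Euclidean to along-network shortest-path distances,
either between arbitrary node pairs (global, E_g) or between each node and
the root (E_r).  Efficiencies and the carbon cost C (gamma * total length)
are normalized against the two extremal designs over the same node set:
the Euclidean minimum spanning tree (cheapest connected network) and the
Delaunay triangulation (near-maximal planar mesh), giving
X_hat = (X - X_MST) / (X_DT - X_MST).
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree as _sp_mst
from scipy.spatial import Delaunay
from scipy.stats import spearmanr

__all__ = [
    "betweenness_to_root",
    "geometric_efficiency",
    "reference_networks",
    "normalized_metrics",
    "width_bc_correlation",
    "bc_distribution",
    "EfficiencyReport",
    "simple_projection",
]


def simple_projection(graph) -> nx.Graph:
    """Project a (multi)graph to a simple graph keeping the shortest
    parallel edge; each kept edge remembers its ``edge_id``."""
    g = nx.Graph()
    for nid, data in graph.nodes(data=True):
        g.add_node(nid, **data)
    for u, v, data in graph.edges(data=True):
        if u == v:
            continue  # self-loops never carry shortest paths
        w = float(data.get("length_um", 1.0))
        if g.has_edge(u, v) and g[u][v]["length_um"] <= w:
            continue
        g.add_edge(u, v, **data)
    return g


def _dijkstra_to_anchors(g: nx.Graph, anchors):
    """Multi-source Dijkstra with deterministic node-id tie-breaking.

    Returns (dist, pred, anchor_of) for every reachable node; each node has
    exactly one predecessor on its chosen shortest path.
    """
    dist: dict = {}
    pred: dict = {}
    anchor_of: dict = {}
    heap = []
    for a in sorted(anchors):
        if a in g:
            dist[a] = 0.0
            pred[a] = None
            anchor_of[a] = a
            heapq.heappush(heap, (0.0, a, None, a))
    while heap:
        d, u, p, root = heapq.heappop(heap)
        if d > dist.get(u, np.inf):
            continue
        for v in sorted(g.neighbors(u)):
            nd = d + g[u][v]["length_um"]
            if nd < dist.get(v, np.inf) - 1e-12:
                dist[v] = nd
                pred[v] = u
                anchor_of[v] = root
                heapq.heappush(heap, (nd, v, u, root))
    return dist, pred, anchor_of


def betweenness_to_root(graph, root_anchors) -> dict:
    """Per-edge count of shortest node-to-root paths traversing the edge.

    ``root_anchors`` is a collection of anchor node ids.  Disconnected
    nodes are flagged in the returned map's companion set.
    Returns ``{edge_id: bc}``; unreachable edges get 0.
    """
    g = simple_projection(graph)
    anchors = [a for a in root_anchors if a in g]
    if not anchors:
        raise ValueError("no root anchor is present in the graph")
    dist, pred, _ = _dijkstra_to_anchors(g, anchors)
    unreachable = set(g.nodes) - set(dist)
    if unreachable:
        warnings.warn(
            f"{len(unreachable)} node(s) unreachable from the root anchors",
            stacklevel=2,
        )
    bc = {data["edge_id"]: 0.0 for _, _, data in graph.edges(data=True)}
    for node in g.nodes:
        if node not in dist:
            continue
        u = node
        while pred[u] is not None:
            v = pred[u]
            bc[g[u][v]["edge_id"]] += 1.0
            u = v
    return bc


def geometric_efficiency(graph, mode: str = "global", root_anchors=None,
                         max_pairs: int = 100_000, seed: int = 0,
                         pair_threshold: int = 2000) -> float:
    """Mean ratio of Euclidean to shortest-path distance.

    mode='global': over node pairs (all pairs up to ``pair_threshold``
    nodes, else ``max_pairs`` seeded random pairs).  mode='root': every
    node against its nearest root anchor.
    """
    g = simple_projection(graph)
    if g.number_of_nodes() < 2:
        raise ValueError("efficiency undefined for fewer than 2 nodes")
    pos = {n: np.asarray(g.nodes[n]["pos"], dtype=float) for n in g.nodes}

    if mode == "root":
        if not root_anchors:
            raise ValueError("mode='root' requires root anchors")
        anchors = [a for a in root_anchors if a in g]
        dist, _, anchor_of = _dijkstra_to_anchors(g, anchors)
        vals = []
        for n in g.nodes:
            if n in anchors or n not in dist or dist[n] <= 0:
                continue
            de = np.hypot(*(pos[n] - pos[anchor_of[n]]))
            vals.append(de / dist[n])
        if not vals:
            raise ValueError("no node-to-root paths available")
        return float(np.mean(vals))

    if mode != "global":
        raise ValueError("mode must be 'global' or 'root'")

    comp = max(nx.connected_components(g), key=len)
    if len(comp) < g.number_of_nodes():
        warnings.warn("graph disconnected: using the largest component",
                      stacklevel=2)
    nodes = sorted(comp)
    n = len(nodes)
    ratios: list[float] = []
    if n * (n - 1) // 2 <= pair_threshold * (pair_threshold - 1) // 2 and n <= pair_threshold:
        for i, u in enumerate(nodes):
            dists = nx.single_source_dijkstra_path_length(g, u, weight="length_um")
            for v in nodes[i + 1:]:
                dsp = dists.get(v)
                if dsp and dsp > 0:
                    ratios.append(float(np.hypot(*(pos[u] - pos[v])) / dsp))
    else:
        rng = np.random.default_rng(seed)
        sources = {}
        for _ in range(max_pairs):
            u, v = nodes[rng.integers(n)], nodes[rng.integers(n)]
            if u == v:
                continue
            sources.setdefault(u, []).append(v)
        for u, targets in sources.items():
            dists = nx.single_source_dijkstra_path_length(g, u, weight="length_um")
            for v in targets:
                dsp = dists.get(v)
                if dsp and dsp > 0:
                    ratios.append(float(np.hypot(*(pos[u] - pos[v])) / dsp))
    if not ratios:
        raise ValueError("no connected node pairs to average over")
    return float(np.mean(ratios))


def reference_networks(points: np.ndarray, node_ids=None):
    """Euclidean MST and Delaunay triangulation over one node set.

    Returns (mst_graph, dt_graph) as networkx graphs whose edges carry
    ``length_um`` and ``edge_id`` and whose nodes carry ``pos``.
    The MST is computed on the Delaunay edge set (which always contains
    the Euclidean MST).  A collinear point set yields the chain MST and
    raises for the triangulation.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    ids = list(node_ids) if node_ids is not None else list(range(len(pts)))

    def build(pairs, tag):
        g = nx.Graph()
        for i, nid in enumerate(ids):
            g.add_node(nid, pos=tuple(pts[i]))
        for k, (i, j) in enumerate(pairs):
            g.add_edge(ids[i], ids[j],
                       length_um=float(np.hypot(*(pts[i] - pts[j]))),
                       edge_id=(tag, k))
        return g

    try:
        tri = Delaunay(pts)
    except Exception:
        # degenerate (collinear) point set: chain MST only, no triangulation
        if np.linalg.matrix_rank(pts - pts.mean(0)) <= 1:
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            mst = build([(order[i], order[i + 1]) for i in range(len(pts) - 1)],
                        "mst")
            warnings.warn("collinear node set: Delaunay triangulation undefined",
                          stacklevel=2)
            return mst, None
        raise
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            pairs.add((min(i, j), max(i, j)))
    pairs = sorted(pairs)
    dt = build(pairs, "dt")

    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    w = np.hypot(*(pts[rows] - pts[cols]).T)
    m = sparse.coo_matrix((w, (rows, cols)), shape=(len(pts), len(pts)))
    mst_m = _sp_mst(m).tocoo()
    mst = build(list(zip(mst_m.row.tolist(), mst_m.col.tolist())), "mst")
    return mst, dt


@dataclass
class EfficiencyReport:
    E_g: float
    E_r: float
    C: float
    E_g_mst: float
    E_g_dt: float
    E_r_mst: float
    E_r_dt: float
    C_mst: float
    C_dt: float
    E_g_hat: float
    E_r_hat: float
    C_hat: float


def _total_length(g) -> float:
    return float(sum(d["length_um"] for *_, d in g.edges(data=True)))


def normalized_metrics(graph, root_anchors, gamma: float = 1.0,
                       seed: int = 0) -> EfficiencyReport:
    """Efficiencies and cost of a snapshot, normalized to its MST and DT."""
    g = simple_projection(graph)
    nodes = sorted(g.nodes)
    pts = np.array([g.nodes[n]["pos"] for n in nodes])
    mst, dt = reference_networks(pts, nodes)

    def metrics(h):
        eg = geometric_efficiency(h, "global", seed=seed)
        er = geometric_efficiency(h, "root", root_anchors=root_anchors, seed=seed)
        return eg, er, gamma * _total_length(h)

    eg, er, cost = metrics(g)
    eg_m, er_m, c_m = metrics(mst)
    eg_d, er_d, c_d = metrics(dt)

    def norm(x, lo, hi):
        if abs(hi - lo) < 1e-12:
            warnings.warn("reference networks coincide: normalization undefined",
                          stacklevel=2)
            return np.nan
        return (x - lo) / (hi - lo)

    return EfficiencyReport(
        E_g=eg, E_r=er, C=cost,
        E_g_mst=eg_m, E_g_dt=eg_d,
        E_r_mst=er_m, E_r_dt=er_d,
        C_mst=c_m, C_dt=c_d,
        E_g_hat=norm(eg, eg_m, eg_d),
        E_r_hat=norm(er, er_m, er_d),
        C_hat=norm(cost, c_m, c_d),
    )


def width_bc_correlation(graph, bc_map: dict, n_boot: int = 1000, seed: int = 0):
    """Spearman rank correlation of edge width against edge BC, with CI."""
    widths, bcs = [], []
    for _, _, data in graph.edges(data=True):
        w = data.get("width_um")
        if w is None or np.isnan(w):
            continue
        widths.append(float(w))
        bcs.append(float(bc_map.get(data["edge_id"], 0.0)))
    widths = np.asarray(widths)
    bcs = np.asarray(bcs)
    if len(widths) < 3 or np.all(widths == widths[0]):
        raise ValueError("width-BC correlation undefined (too few or constant widths)")
    rho = float(spearmanr(widths, bcs).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(widths), len(widths))
        if np.all(widths[idx] == widths[idx][0]) or np.all(bcs[idx] == bcs[idx][0]):
            continue
        boots.append(spearmanr(widths[idx], bcs[idx]).statistic)
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    return rho, ci


def bc_distribution(bc_map: dict, n_bins: int = 20, x_min: float | None = None):
    """Log-binned BC histogram plus a maximum-likelihood tail fit.

    The tail above ``x_min`` (default: the median positive BC) is fitted
    with a continuous power law, exponent
    ``alpha = 1 + n / sum(log(x / x_min))``, and compared against an
    exponential tail by log-likelihood.  Returns a dict with the histogram
    and the fit summary; with fewer than 100 edges only the histogram is
    produced.
    """
    vals = np.asarray([v for v in bc_map.values() if v > 0], dtype=float)
    if len(vals) == 0:
        raise ValueError("no positive BC values")
    edges = np.logspace(np.log10(vals.min()), np.log10(vals.max() + 1e-9),
                        n_bins + 1)
    hist, _ = np.histogram(vals, bins=edges)
    out = {"bin_edges": edges, "counts": hist}
    if len(vals) < 100:
        return out
    if x_min is None:
        x_min = float(np.median(vals))
    tail = vals[vals >= x_min]
    n = len(tail)
    logs = np.log(tail / x_min)
    s = float(logs.sum())
    alpha = 1.0 + n / max(s, 1e-12)
    ll_pl = n * np.log(alpha - 1) - n * np.log(x_min) - alpha * s
    lam = 1.0 / max(float((tail - x_min).mean()), 1e-12)
    ll_exp = n * np.log(lam) - lam * float((tail - x_min).sum())
    out.update(
        x_min=x_min, tail_exponent=alpha, n_tail=n,
        loglik_powerlaw=float(ll_pl), loglik_exponential=float(ll_exp),
        lr_powerlaw_vs_exponential=float(ll_pl - ll_exp),
    )
    return out
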