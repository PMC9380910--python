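"""Rooted progression models: cluster-centroid graphs on the principal tree,
sample projection, pseudo-time ordering and per-subject dispersion.

The fitted principal tree supplies the geometry; the clustering supplies the
coarse states. Cluster centroids are projected onto the tree, joined when no
other centroid lies between them along the tree, rooted at healthy-origin
leaves, and each root-to-endpoint path becomes a progression path. A sample's
pseudo-time on a path is the (optionally branch-scaled) curve distance from
the root to the sample's closest point on the path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tree import PrincipalTree, mst_kruskal

logger = logging.getLogger(__name__)

MIN_SERIAL_SAMPLES = 5
MAD_SCALE = 1.5  # 1.5 x MAD as a robust one-standard-deviation analogue


@dataclass
class TreeProjection:
    """Closest point of a sample on the piecewise-linear latent tree."""

    edge: tuple[int, int]
    offset: float          # proportion along edge, measured from edge[0]
    point: np.ndarray      # latent coordinates of the projection
    sq_dist: float


@dataclass
class Path:
    """One root-to-endpoint progression path over cluster nodes."""

    path_id: int
    clusters: list[int]            # ordered, root first
    polyline: np.ndarray           # (n_vertices, d) latent waypoints
    seg_model_edge: np.ndarray     # model-edge index of each polyline segment
    seg_raw_len: np.ndarray        # raw Euclidean length of each segment

    @property
    def root(self) -> int:
        return self.clusters[0]

    @property
    def endpoint(self) -> int:
        return self.clusters[-1]


@dataclass
class ProgressionModel:
    tree: PrincipalTree
    graph: nx.Graph                       # nodes = cluster ids; edge attr raw_length
    centroid_proj: dict[int, TreeProjection]
    origins: list[int]
    paths: list[Path] = field(default_factory=list)
    branch_scale: dict[tuple[int, int], float] = field(default_factory=dict)

    def edge_scale(self, a: int, b: int) -> float:
        return self.branch_scale.get((min(a, b), max(a, b)), 1.0)


def project_to_tree(point: np.ndarray, tree: PrincipalTree) -> TreeProjection:
    """Closest point over all tree edge segments; ties toward the lower-indexed
    edge; a projection landing on an endpoint is reported with offset 0 from
    that endpoint."""
    if not tree.edges:
        raise ValueError("tree has no edges")
    p = np.asarray(point, dtype=float)
    best: TreeProjection | None = None
    for i, j in tree.edges:  # edges are (i, j) with i < j, in Kruskal order
        a, b = tree.Z[:, i], tree.Z[:, j]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        q = a + t * ab
        d2 = float(((p - q) ** 2).sum())
        if best is None or d2 < best.sq_dist - 1e-15:
            if t == 1.0:
                edge, t = (j, i), 0.0
            else:
                edge = (i, j)
            best = TreeProjection(edge=edge, offset=t, point=q, sq_dist=d2)
    return best


def _arc_distance_matrix(tree: PrincipalTree, projs: list[TreeProjection]) -> np.ndarray:
    """Pairwise curve distances along the tree between projected points."""
    g = tree.graph()
    node_dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    k = len(projs)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = _pair_arc(tree, g, node_dist, projs[a], projs[b])
    return out


def _pair_arc(tree, g, node_dist, pa: TreeProjection, pb: TreeProjection) -> float:
    ea, eb = pa.edge, pb.edge
    if set(ea) == set(eb):
        return float(np.linalg.norm(pa.point - pb.point))
    best = np.inf
    for u in ea:
        du = float(np.linalg.norm(pa.point - tree.Z[:, u]))
        for v in eb:
            dv = float(np.linalg.norm(pb.point - tree.Z[:, v]))
            best = min(best, du + node_dist[u][v] + dv)
    return best


def build_progression_graph(
    tree: PrincipalTree,
    labels: np.ndarray,
    groups: pd.Series | np.ndarray | None = None,
    healthy_label: str = "HC",
) -> ProgressionModel:
    """Project cluster centroids onto the tree and join adjacent ones.

    Two centroids are connected iff no third centroid lies strictly between
    them along the tree; edge length is the curve distance between the two
    projections. Origin (root) clusters are the leaf clusters of the centroid
    graph richest in healthy-control samples.
    """
    labels = np.asarray(labels)
    cluster_ids = sorted(int(c) for c in np.unique(labels))
    projs: dict[int, TreeProjection] = {}
    for c in cluster_ids:
        centroid = tree.Y[:, labels == c].mean(axis=1)
        projs[c] = project_to_tree(centroid, tree)
    arc = _arc_distance_matrix(tree, [projs[c] for c in cluster_ids])

    # Adjacency: centroids joined when no other centroid lies between them
    # along the tree. Realised as the MST of the curve-distance matrix: when a
    # third centroid c sits between a and b, arc(a,b) = arc(a,c) + arc(c,b)
    # and Kruskal never keeps the long edge; near junctions (where strict
    # betweenness fails for all three incident pairs) the MST resolves the
    # would-be cycle by dropping its longest edge, keeping the model a tree.
    g = nx.Graph()
    g.add_nodes_from(cluster_ids)
    k = len(cluster_ids)
    tol = 1e-9 + 1e-6 * (arc.max() if k > 1 else 0.0)
    for i, j in mst_kruskal(arc):
        if arc[i, j] <= tol:
            logger.warning(
                "clusters %s and %s project to the same point; merged node",
                cluster_ids[i], cluster_ids[j],
            )
        g.add_edge(cluster_ids[i], cluster_ids[j], raw_length=float(arc[i, j]))

    origins = _origin_leaves(g, labels, groups, healthy_label) if groups is not None else []
    return ProgressionModel(tree=tree, graph=g, centroid_proj=projs, origins=origins)


def _origin_leaves(g: nx.Graph, labels, groups, healthy_label: str) -> list[int]:
    """Disease-origin clusters: the healthy-dominated extremes of the graph.

    Every cluster with a healthy-control majority is an origin candidate; of
    those, the leaves of the healthy-induced subgraph are kept (an HC cluster
    wedged between two other HC clusters is a way-station, not an origin).
    Falls back to the single most HC-rich leaf when no cluster has an HC
    majority."""
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    frac = {}
    for v in g.nodes:
        members = labels == v
        frac[v] = float(np.mean(groups[members] == healthy_label)) if members.any() else 0.0
    healthy = [v for v in g.nodes if frac[v] >= 0.5]
    if healthy:
        sub = g.subgraph(healthy)
        origins = [v for v in healthy if sub.degree(v) <= 1]
        return sorted(origins)
    leaves = [v for v in g.nodes if g.degree(v) == 1] or list(g.nodes)
    best = max(frac[v] for v in leaves)
    return sorted(v for v in leaves if frac[v] == best)


def extract_paths(model: ProgressionModel, root: int | None = None) -> list[Path]:
    """Root-to-leaf progression paths over the cluster graph.

    With an explicit ``root`` cluster: one path per other leaf. Otherwise the
    healthy-origin rule applies: one path from every origin leaf to every
    non-origin leaf (two origins x two endpoints gives four paths).
    """
    g = model.graph
    if root is not None:
        if root not in g:
            raise ValueError(f"designated root {root} is not a cluster node")
        roots = [root]
    else:
        if not model.origins:
            raise ValueError("no origin clusters known; pass root= or group labels")
        roots = model.origins
    leaves = [v for v in g.nodes if g.degree(v) == 1] or list(g.nodes)
    paths: list[Path] = []
    pid = 0
    for r in roots:
        for leaf in leaves:
            if leaf == r or leaf in roots:
                continue
            clusters = nx.shortest_path(g, r, leaf, weight="raw_length")
            paths.append(_build_path(model, pid, clusters))
            pid += 1
    model.paths = paths
    return paths


def _build_path(model: ProgressionModel, pid: int, clusters: list[int]) -> Path:
    """Geometric polyline of a cluster path along the tree."""
    tree = model.tree
    g = tree.graph()
    pts: list[np.ndarray] = []
    for ca, cb in zip(clusters[:-1], clusters[1:]):
        pa, pb = model.centroid_proj[ca], model.centroid_proj[cb]
        way = _tree_waypoints(tree, g, pa, pb)
        if pts:
            way = way[1:]  # shared joint
        pts.extend(np.asarray(p) for p in way)
    poly = np.vstack(pts)
    # remove zero-length duplicate waypoints
    keep = [0] + [i for i in range(1, len(poly)) if np.linalg.norm(poly[i] - poly[i - 1]) > 1e-12]
    poly = poly[keep]
    seg_raw = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    # assign each polyline segment to its model edge by cumulative centroid arcs
    cum_centroid = np.concatenate(
        [[0.0], np.cumsum([model.graph.edges[a, b]["raw_length"]
                           for a, b in zip(clusters[:-1], clusters[1:])])]
    )
    mid = np.concatenate([[0.0], np.cumsum(seg_raw)])
    seg_mid = (mid[:-1] + mid[1:]) / 2.0
    seg_model = np.clip(np.searchsorted(cum_centroid, seg_mid, side="right") - 1,
                        0, len(clusters) - 2)
    return Path(path_id=pid, clusters=list(clusters), polyline=poly,
                seg_model_edge=seg_model.astype(int), seg_raw_len=seg_raw)


def _tree_waypoints(tree: PrincipalTree, g: nx.Graph,
                    pa: TreeProjection, pb: TreeProjection) -> list[np.ndarray]:
    """Waypoints of the tree curve from projection pa to projection pb."""
    if set(pa.edge) == set(pb.edge):
        return [pa.point, pb.point]
    node_dist = {}
    best = (np.inf, None, None)
    for u in pa.edge:
        du = float(np.linalg.norm(pa.point - tree.Z[:, u]))
        for v in pb.edge:
            dv = float(np.linalg.norm(pb.point - tree.Z[:, v]))
            try:
                dl, nodes = nx.single_source_dijkstra(g, u, v, weight="length")
            except nx.NetworkXNoPath:  # pragma: no cover - tree is connected
                continue
            total = du + dl + dv
            if total < best[0]:
                best = (total, nodes, (u, v))
    _, nodes, _ = best
    return [pa.point] + [tree.Z[:, n] for n in nodes] + [pb.point]


def project_to_path(points: np.ndarray, path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Project latent points onto a path polyline.

    Returns (raw arc positions from the path root, squared distances)."""
    pts = np.asarray(points, dtype=float)
    poly = path.polyline
    cum = np.concatenate([[0.0], np.cumsum(path.seg_raw_len)])
    n = pts.shape[0]
    arc = np.zeros(n)
    d2 = np.full(n, np.inf)
    for s in range(len(poly) - 1):
        a, b = poly[s], poly[s + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = np.zeros(n) if denom == 0 else np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        q = a + t[:, None] * ab
        dd = ((pts - q) ** 2).sum(axis=1)
        better = dd < d2 - 1e-15
        arc[better] = cum[s] + t[better] * path.seg_raw_len[s]
        d2[better] = dd[better]
    return arc, d2


def progression_distance(arc: np.ndarray, path: Path, model: ProgressionModel) -> np.ndarray:
    """Branch-scaled curve distance from the root for raw arc positions."""
    arc = np.atleast_1d(np.asarray(arc, dtype=float))
    cum = np.concatenate([[0.0], np.cumsum(path.seg_raw_len)])
    scales = np.array([
        model.edge_scale(path.clusters[e], path.clusters[e + 1])
        for e in path.seg_model_edge
    ])
    scaled_seg = path.seg_raw_len * scales
    scaled_cum = np.concatenate([[0.0], np.cumsum(scaled_seg)])
    seg = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(path.seg_raw_len) - 1)
    frac = np.where(path.seg_raw_len[seg] > 0, (arc - cum[seg]) / np.where(
        path.seg_raw_len[seg] > 0, path.seg_raw_len[seg], 1.0), 0.0)
    return scaled_cum[seg] + frac * scaled_seg[seg]


def order_pseudotime(sample_ids: list[str], distances: np.ndarray) -> list[str]:
    """Samples sorted by progression distance, ties by sample id."""
    order = sorted(range(len(sample_ids)), key=lambda i: (distances[i], sample_ids[i]))
    return [sample_ids[i] for i in order]


@dataclass
class SubjectTrajectory:
    subject_id: str
    distances: np.ndarray
    median: float
    dispersion: float  # 1.5 x MAD


def subject_dispersion(
    meta: pd.DataFrame,
    distances: pd.Series,
    min_serial: int = MIN_SERIAL_SAMPLES,
) -> list[SubjectTrajectory]:
    """Per-subject robust spread of progression distances.

    Subjects with fewer than ``min_serial`` serial samples are omitted (a
    handful of samples cannot support a variance estimate)."""
    out: list[SubjectTrajectory] = []
    merged = meta.set_index("sample_id")
    for subject, rows in merged.groupby("subject_id", sort=True):
        ids = [s for s in rows.index if s in distances.index]
        if len(ids) < min_serial:
            logger.info("subject %s has %d samples (< %d); omitted", subject, len(ids), min_serial)
            continue
        d = distances.loc[ids].to_numpy(dtype=float)
        med = float(np.median(d))
        mad = float(np.median(np.abs(d - med)))
        out.append(SubjectTrajectory(str(subject), d, med, MAD_SCALE * mad))
    return out


def equalize_origin_scale(model: ProgressionModel) -> dict[tuple[int, int], float]:
    """Scale for the shorter origin branch so both origins sit at the same
    curve distance from their junction (an interpretation of making the
    progression distance independent of the disease origin used)."""
    if len(model.origins) != 2:
        raise ValueError("origin equalisation needs exactly two origin clusters")
    a, b = model.origins
    # branch = first edge out of each origin toward the rest of the graph
    lengths = {}
    for o in (a, b):
        nbr = next(iter(model.graph.neighbors(o)))
        lengths[o] = (model.graph.edges[o, nbr]["raw_length"], nbr)
    (la, na), (lb, nb) = lengths[a], lengths[b]
    if la == lb:
        return {}
    if la < lb:
        short, nbr, factor = a, na, lb / la if la > 0 else 1.0
    else:
        short, nbr, factor = b, nb, la / lb if lb > 0 else 1.0
    return {(min(short, nbr), max(short, nbr)): float(factor)}
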