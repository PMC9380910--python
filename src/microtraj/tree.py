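"""Principal-tree learning by reversed graph embedding (DDRTree-style).

The data are modelled as noisy emissions from points living on a latent tree:
a linear orthonormal map W lifts d-dimensional latent coordinates back to the
input space, latent sample positions Y are softly assigned to latent tree
nodes Z, and the tree itself is a minimum spanning tree over Z whose total
squared length is penalised. The objective

    sum_n ||x_n - W y_n||^2
    + (lambda/2) sum_ij b_ij ||z_i - z_j||^2
    + gamma sum_ij p_ij (||y_i - z_j||^2 + sigma log p_ij)

is minimised by alternating exact block updates: (W, Y) by a Procrustes /
ridge pair, Z by a Laplacian-regularised linear solve, P analytically
(softmax), and the tree edges b by Kruskal's algorithm on squared latent
distances. Every block is an exact minimiser given the others, so the
objective is non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

DEFAULT_SIGMA = 0.5
DEFAULT_LAMBDA = 150.0
DEFAULT_GAMMA = 2.0
DEFAULT_DIM = 3
DEFAULT_PRUNE_FRAC = 0.05
DEFAULT_SIGMA_GRID = (0.05, 0.1, 0.2, 0.5, 1.0)
DEFAULT_LAMBDA_GRID = (5.0, 15.0, 50.0, 150.0, 500.0)


def mst_kruskal(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimum spanning tree of a symmetric cost matrix by Kruskal's algorithm.

    Ties break deterministically by (cost, smaller index pair). Returns edges
    as (i, j) with i < j.
    """
    cost = np.asarray(cost, dtype=float)
    n = cost.shape[0]
    if cost.shape != (n, n) or not np.allclose(cost, cost.T, atol=1e-12, equal_nan=False):
        raise ValueError("cost matrix must be symmetric")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    if n <= 1:
        return []
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, cost[iu, ju]))
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int]] = []
    for e in order:
        i, j = int(iu[e]), int(ju[e])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j))
            if len(edges) == n - 1:
                break
    return edges


def soft_assignments(Y: np.ndarray, Z: np.ndarray, sigma: float) -> np.ndarray:
    """Row-normalised p_ij ~ exp(-||y_i - z_j||^2 / sigma), log-sum-exp guarded."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = _sqdist(Y, Z)
    logits = -d2 / sigma
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between columns of A and of B."""
    aa = (A * A).sum(axis=0)
    bb = (B * B).sum(axis=0)
    return np.maximum(aa[:, None] + bb[None, :] - 2.0 * (A.T @ B), 0.0)


def projection_step(
    X: np.ndarray,
    Z: np.ndarray,
    P: np.ndarray,
    gamma: float,
    W_init: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Update (W, Y) for fixed Z and P.

    Alternates the closed forms y_i = (W^T x_i + gamma * sum_j p_ij z_j)/(1+gamma)
    and the orthogonal-Procrustes update W = U V^T from the SVD of X Y^T;
    each is exact so the objective cannot increase. X, Z are column-major
    (D x N and d x N).
    """
    d = Z.shape[0]
    if W_init is None:
        # PCA basis of X as the starting frame
        Xc = X - X.mean(axis=1, keepdims=True)
        U, _, _ = np.linalg.svd(Xc, full_matrices=False)
        W = U[:, :d]
    else:
        W = W_init
    C = Z @ P.T  # column i = sum_j p_ij z_j
    prev = np.inf
    Y = (W.T @ X + gamma * C) / (1.0 + gamma)
    for _ in range(max_iter):
        U, _, Vt = np.linalg.svd(X @ Y.T, full_matrices=False)
        W = U @ Vt
        Y = (W.T @ X + gamma * C) / (1.0 + gamma)
        crit = float(((X - W @ Y) ** 2).sum() + gamma * ((Y - C) ** 2).sum())
        if prev - crit < tol * max(abs(prev), 1.0):
            break
        prev = crit
    return W, Y


def _z_update(Y: np.ndarray, P: np.ndarray, edges: list[tuple[int, int]],
              lam: float, gamma: float) -> np.ndarray:
    """Exact minimiser of the Z blocks: Z (lam L + gamma diag(m)) = gamma Y P."""
    n = P.shape[1]
    L = np.zeros((n, n))
    for i, j in edges:
        L[i, i] += 1.0
        L[j, j] += 1.0
        L[i, j] -= 1.0
        L[j, i] -= 1.0
    m = P.sum(axis=0)
    A = lam * L + gamma * np.diag(m)
    # A is symmetric positive definite for lam, gamma > 0 and connected support
    return np.linalg.solve(A, (gamma * (Y @ P)).T).T


def tree_objective(
    X: np.ndarray, W: np.ndarray, Y: np.ndarray, Z: np.ndarray,
    P: np.ndarray, edges: list[tuple[int, int]],
    sigma: float, gamma: float, lam: float,
) -> float:
    recon = float(((X - W @ Y) ** 2).sum())
    length = sum(float(((Z[:, i] - Z[:, j]) ** 2).sum()) for i, j in edges)
    d2 = _sqdist(Y, Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(P > 0, P * np.log(P), 0.0).sum()
    return recon + lam * length + gamma * float((P * d2).sum()) + gamma * sigma * float(ent)


@dataclass
class PrincipalTree:
    """Fitted principal tree: latent coordinates, tree nodes, and MST edges."""

    W: np.ndarray           # (D, d), orthonormal columns
    Y: np.ndarray           # (d, N) latent sample coordinates
    Z: np.ndarray           # (d, N) latent tree-node coordinates
    edges: list[tuple[int, int]]
    P: np.ndarray           # (N, N) soft assignments, rows sum to 1
    sigma: float
    gamma: float
    lambda_tree: float
    d: int
    mean: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    def graph(self) -> nx.Graph:
        """Latent tree as a networkx graph with Euclidean edge lengths."""
        g = nx.Graph()
        g.add_nodes_from(range(self.Z.shape[1]))
        for i, j in self.edges:
            g.add_edge(i, j, length=float(np.linalg.norm(self.Z[:, i] - self.Z[:, j])))
        return g


def fit_principal_tree(
    X_selected: np.ndarray,
    d: int = DEFAULT_DIM,
    gamma: float = DEFAULT_GAMMA,
    sigma: float = DEFAULT_SIGMA,
    lambda_tree: float = DEFAULT_LAMBDA,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> PrincipalTree:
    """Alternating structure optimisation of the principal-tree objective.

    ``X_selected`` is samples x features; one latent tree node per sample.
    Initialisation: top-d principal-component scores for both Y and Z.
    """
    if sigma <= 0 or lambda_tree <= 0 or gamma <= 0:
        raise ValueError("sigma, lambda_tree and gamma must be > 0")
    Xs = np.asarray(X_selected, dtype=float)
    n = Xs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = min(d, Xs.shape[1], n)
    mean = Xs.mean(axis=0)
    X = (Xs - mean).T  # D x N

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = U[:, :d]
    Y = W.T @ X
    Z = Y.copy()
    edges = mst_kruskal(_sqdist(Z, Z))
    P = soft_assignments(Y, Z, sigma)

    trace = [tree_objective(X, W, Y, Z, P, edges, sigma, gamma, lambda_tree)]
    converged = False
    for _ in range(max_iter):
        W, Y = projection_step(X, Z, P, gamma, W_init=W)
        Z = _z_update(Y, P, edges, lambda_tree, gamma)
        P = soft_assignments(Y, Z, sigma)
        edges = mst_kruskal(_sqdist(Z, Z))
        obj = tree_objective(X, W, Y, Z, P, edges, sigma, gamma, lambda_tree)
        rel = abs(trace[-1] - obj) / max(abs(trace[-1]), 1e-12)
        trace.append(obj)
        if rel < tol:
            converged = True
            break
    return PrincipalTree(
        W=W, Y=Y, Z=Z, edges=edges, P=P, sigma=sigma, gamma=gamma,
        lambda_tree=lambda_tree, d=d, mean=mean,
        objective_trace=trace, converged=converged,
    )


def tune_elbow(
    X: np.ndarray,
    sigma_grid=None,
    lambda_grid=None,
    d: int = DEFAULT_DIM,
    gamma: float = DEFAULT_GAMMA,
    max_iter: int = 30,
) -> tuple[float, float]:
    """Elbow-method choice of (sigma, lambda): per parameter, fit over its grid
    and take the point of maximum curvature (largest discrete second
    difference) of the final objective; the other parameter is held at its
    default while tuning. Omitted grids fall back to the defaults (0.5, 150).
    """
    if sigma_grid is None and lambda_grid is None:
        return DEFAULT_SIGMA, DEFAULT_LAMBDA
    sigma = DEFAULT_SIGMA
    if sigma_grid is not None:
        objs = [fit_principal_tree(X, d=d, gamma=gamma, sigma=s,
                                   lambda_tree=DEFAULT_LAMBDA, max_iter=max_iter
                                   ).objective_trace[-1] for s in sigma_grid]
        sigma = float(sigma_grid[elbow_index(objs)])
    lam = DEFAULT_LAMBDA
    if lambda_grid is not None:
        objs = [fit_principal_tree(X, d=d, gamma=gamma, sigma=sigma,
                                   lambda_tree=l, max_iter=max_iter
                                   ).objective_trace[-1] for l in lambda_grid]
        lam = float(lambda_grid[elbow_index(objs)])
    return sigma, lam


def elbow_index(curve) -> int:
    """Index of maximum discrete curvature; midpoint with a warning if the
    curve is too short or flat."""
    f = np.asarray(curve, dtype=float)
    if f.size < 3:
        warnings.warn("grid too small for an elbow; returning its midpoint")
        return f.size // 2
    second = f[:-2] - 2.0 * f[1:-1] + f[2:]
    if np.allclose(second, 0.0):
        warnings.warn("flat objective curve; returning the grid midpoint")
        return f.size // 2
    return int(np.argmax(second)) + 1


# ---------------------------------------------------------------- topology

def prune_minor_branches(
    g: nx.Graph, prune_frac: float = DEFAULT_PRUNE_FRAC
) -> tuple[nx.Graph, dict[int, int]]:
    """Remove hair-like twig branches carrying almost no tree nodes.

    A per-sample principal tree always carries micro-branches where one or
    two nodes sit slightly off the backbone; a leaf whose run up to the
    nearest junction holds fewer than ``prune_frac`` of all nodes (at least
    2) is folded back onto its attachment node. Real branches are populated
    by many sample nodes and are never touched. Returns the pruned backbone
    and a map from every removed node to the backbone node it attaches to.
    Iterates until stable.
    """
    g = g.copy()
    attach: dict[int, int] = {}
    threshold = max(2, int(round(prune_frac * g.number_of_nodes())))
    while True:
        leaves = [v for v in g.nodes if g.degree(v) == 1]
        if len(leaves) <= 2:
            break
        removed_any = False
        branches = {leaf: _leaf_branch(g, leaf) for leaf in leaves}
        # prune the thinnest minor twig first; recompute after each removal
        for leaf in sorted(leaves, key=lambda v: len(branches[v][1])):
            run = branches[leaf][1]
            if len(run) - 1 >= threshold or g.degree(run[-1]) < 3:
                continue  # keep populated branches; never prune a bare path
            junction = run[-1]
            for v in run[:-1]:
                attach[v] = junction
                g.remove_node(v)
            removed_any = True
            break
        if not removed_any:
            break
    # chase attachment chains down to surviving nodes
    for v in list(attach):
        a = attach[v]
        while a in attach:
            a = attach[a]
        attach[v] = a
    return g, attach


def _leaf_branch(g: nx.Graph, leaf: int) -> tuple[float, list[int]]:
    """Walk from a leaf to the first junction (degree >= 3) or opposite leaf.

    Returns (arc length, node run ending at the junction)."""
    run = [leaf]
    length = 0.0
    prev, cur = None, leaf
    while g.degree(cur) <= 2:
        nbrs = [u for u in g.neighbors(cur) if u != prev]
        if not nbrs:
            break
        nxt = nbrs[0]
        length += g.edges[cur, nxt]["length"]
        prev, cur = cur, nxt
        run.append(cur)
    return length, run


def _tree_diameter(g: nx.Graph) -> float:
    """Longest path length in the tree (double sweep)."""
    if g.number_of_nodes() < 2:
        return 0.0
    start = next(iter(g.nodes))
    d0 = nx.single_source_dijkstra_path_length(g, start, weight="length")
    far = max(d0, key=d0.get)
    d1 = nx.single_source_dijkstra_path_length(g, far, weight="length")
    return max(d1.values())


def count_leaves(tree: PrincipalTree, prune_frac: float = DEFAULT_PRUNE_FRAC) -> int:
    """Number of leaves of the pruned backbone tree."""
    backbone, _ = prune_minor_branches(tree.graph(), prune_frac)
    return sum(1 for v in backbone.nodes if backbone.degree(v) == 1)


def branch_labels(tree: PrincipalTree, prune_frac: float = DEFAULT_PRUNE_FRAC) -> np.ndarray:
    """Per-node branch id from the pruned backbone.

    Branches are the maximal backbone segments between topological vertices
    (junctions or leaves); pruned twig nodes inherit the branch of their
    attachment node.
    """
    backbone, attach = prune_minor_branches(tree.graph(), prune_frac)
    vertices = {v for v in backbone.nodes if backbone.degree(v) != 2}
    if not vertices:  # cycle-free degenerate case: single path with no endpoints?
        vertices = {next(iter(backbone.nodes))}
    label = {}
    branch_id = 0
    visited_edges = set()
    for v in sorted(vertices):
        for u in sorted(backbone.neighbors(v)):
            if (v, u) in visited_edges or (u, v) in visited_edges:
                continue
            # walk the segment to the next topological vertex
            seg = [v]
            prev, cur = v, u
            visited_edges.add((v, u))
            while cur not in vertices:
                seg.append(cur)
                nbrs = [w for w in backbone.neighbors(cur) if w != prev]
                prev, cur = cur, nbrs[0]
                visited_edges.add((prev, cur))
            seg.append(cur)
            for node in seg[1:-1]:
                label[node] = branch_id
            # endpoints may border several branches; give them one deterministically
            label.setdefault(seg[0], branch_id)
            label.setdefault(seg[-1], branch_id)
            branch_id += 1
    n = tree.Z.shape[1]
    out = np.full(n, -1, dtype=int)
    for v in backbone.nodes:
        out[v] = label.get(v, -1)
    for v, a in attach.items():
        out[v] = label.get(a, -1)
    return out


class DDRTree(TransformerMixin, BaseEstimator):
    """scikit-learn wrapper around the principal-tree fit.

    ``fit_transform(X)`` returns the latent sample coordinates (n_samples x
    dim). Fitted attributes: ``tree_`` (the :class:`PrincipalTree`),
    ``embedding_``, ``nodes_``, ``edges_``, ``objective_trace_``.
    """

    def __init__(
        self,
        dim: int = DEFAULT_DIM,
        gamma: float = DEFAULT_GAMMA,
        sigma: float = DEFAULT_SIGMA,
        lambda_tree: float = DEFAULT_LAMBDA,
        tol: float = 1e-5,
        max_iter: int = 100,
    ):
        self.dim = dim
        self.gamma = gamma
        self.sigma = sigma
        self.lambda_tree = lambda_tree
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float)
        self.tree_ = fit_principal_tree(
            X, d=self.dim, gamma=self.gamma, sigma=self.sigma,
            lambda_tree=self.lambda_tree, tol=self.tol, max_iter=self.max_iter,
        )
        self.embedding_ = self.tree_.Y.T
        self.nodes_ = self.tree_.Z.T
        self.edges_ = self.tree_.edges
        self.objective_trace_ = self.tree_.objective_trace
        return self

    def transform(self, X):
        """Least-squares latent coordinates W^T (x - mean) for new samples."""
        check_is_fitted(self, "tree_")
        X = validate_data(self, X, dtype=float, reset=False)
        return (X - self.tree_.mean) @ self.tree_.W
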