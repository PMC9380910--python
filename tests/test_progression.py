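import networkx as nx
import numpy as np
import pandas as pd
import pytest

from microtraj import progression
from microtraj.tree import PrincipalTree


def _path_tree(points):
    """PrincipalTree stub along a chain of latent points (d x n array-like)."""
    Z = np.asarray(points, dtype=float)
    n = Z.shape[1]
    edges = [(i, i + 1) for i in range(n - 1)]
    return PrincipalTree(
        W=np.eye(Z.shape[0]), Y=Z.copy(), Z=Z, edges=edges,
        P=np.eye(n), sigma=0.1, gamma=2.0, lambda_tree=1.0, d=Z.shape[0],
        mean=np.zeros(Z.shape[0]),
    )


class TestProjectToTree:
    def test_node_projection_offset_zero(self):
        tree = _path_tree([[0.0, 1.0, 2.0], [0.0, 0.0, 0.0]])
        proj = progression.project_to_tree(np.array([1.0, 0.0]), tree)
        assert proj.offset == 0.0
        assert proj.sq_dist == pytest.approx(0.0)

    def test_midpoint_projection(self):
        tree = _path_tree([[0.0, 2.0], [0.0, 0.0]])
        proj = progression.project_to_tree(np.array([1.0, 5.0]), tree)
        assert proj.offset == pytest.approx(0.5)
        np.testing.assert_allclose(proj.point, [1.0, 0.0])

    def test_beyond_endpoint_clamps(self):
        tree = _path_tree([[0.0, 1.0], [0.0, 0.0]])
        proj = progression.project_to_tree(np.array([5.0, 0.0]), tree)
        np.testing.assert_allclose(proj.point, [1.0, 0.0])

    def test_idempotent_reprojection(self):
        tree = _path_tree([[0.0, 1.0, 3.0], [0.0, 1.0, 0.5]])
        p1 = progression.project_to_tree(np.array([0.7, 0.9]), tree)
        p2 = progression.project_to_tree(p1.point, tree)
        np.testing.assert_allclose(p1.point, p2.point, atol=1e-12)


def _star_model():
    """Y-shaped latent tree with labelled clusters at the three tips + centre."""
    #       2 (0,2)
    #       |
    # 0 --- c --- 1      c = (0,0), 0 = (-2,0), 1 = (2,0)
    Z = np.array([[-2.0, -1.0, 0.0, 1.0, 2.0, 0.0, 0.0],
                  [0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 2.0]])
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (2, 5), (5, 6)]
    tree = PrincipalTree(W=np.eye(2), Y=Z.copy(), Z=Z, edges=edges, P=np.eye(7),
                         sigma=0.1, gamma=2.0, lambda_tree=1.0, d=2,
                         mean=np.zeros(2))
    labels = np.array([1, 1, 2, 3, 3, 4, 4])
    groups = np.array(["HC", "HC", "B1", "B2", "B2", "B3", "B3"])
    return tree, labels, groups


class TestProgressionGraph:
    def test_collinear_arc_adjacency(self):
        tree = _path_tree([[0.0, 1.0, 3.0]])
        labels = np.array([1, 2, 3])
        model = progression.build_progression_graph(tree, labels)
        assert set(model.graph.edges) == {(1, 2), (2, 3)}
        assert model.graph.edges[1, 2]["raw_length"] == pytest.approx(1.0)
        assert model.graph.edges[2, 3]["raw_length"] == pytest.approx(2.0)

    def test_single_cluster_no_edges(self):
        tree = _path_tree([[0.0, 1.0]])
        model = progression.build_progression_graph(tree, np.array([1, 1]))
        assert model.graph.number_of_edges() == 0

    def test_star_topology_follows_branches(self):
        tree, labels, groups = _star_model()
        model = progression.build_progression_graph(tree, labels, groups=groups)
        assert nx.is_tree(model.graph)
        assert set(model.graph.edges) == {(1, 2), (2, 3), (2, 4)}
        assert model.origins == [1]


class TestPaths:
    def test_chain_rooted_at_end(self):
        tree = _path_tree([[0.0, 1.0, 2.0, 3.0]])
        labels = np.array([1, 2, 3, 4])
        model = progression.build_progression_graph(tree, labels)
        paths = progression.extract_paths(model, root=1)
        assert len(paths) == 1
        assert paths[0].clusters == [1, 2, 3, 4]

    def test_star_rooted_at_leaf_two_paths(self):
        tree, labels, groups = _star_model()
        model = progression.build_progression_graph(tree, labels, groups=groups)
        paths = progression.extract_paths(model, root=1)
        assert sorted(p.clusters for p in paths) == [[1, 2, 3], [1, 2, 4]]

    def test_missing_root_error(self):
        tree = _path_tree([[0.0, 1.0]])
        model = progression.build_progression_graph(tree, np.array([1, 2]))
        with pytest.raises(ValueError):
            progression.extract_paths(model, root=99)


class TestDistances:
    def test_root_projection_zero_and_scaling(self):
        tree = _path_tree([[0.0, 1.0, 3.0]])
        labels = np.array([1, 2, 3])
        model = progression.build_progression_graph(tree, labels)
        paths = progression.extract_paths(model, root=1)
        path = paths[0]
        model.branch_scale[(1, 2)] = 1.66
        arc = np.array([0.0, 1.0, 3.0])
        dist = progression.progression_distance(arc, path, model)
        assert dist[0] == pytest.approx(0.0)
        assert dist[1] == pytest.approx(1.66)
        assert dist[2] == pytest.approx(1.66 + 2.0)

    def test_distances_increase_along_path(self):
        tree = _path_tree([[0.0, 1.0, 2.0, 4.0]])
        labels = np.array([1, 1, 2, 2])
        model = progression.build_progression_graph(tree, labels)
        path = progression.extract_paths(model, root=1)[0]
        pts = np.array([[0.2], [1.1], [2.5], [3.9]])
        arc, _ = progression.project_to_path(pts, path)
        dist = progression.progression_distance(arc, path, model)
        assert np.all(np.diff(dist) > 0)

    def test_order_pseudotime_ties_by_id(self):
        order = progression.order_pseudotime(["b", "a", "c"], np.array([0.9, 0.4, 0.4]))
        assert order == ["a", "c", "b"]


class TestSubjectDispersion:
    def _meta(self, subject_sizes):
        rows = []
        i = 0
        for subj, m in subject_sizes.items():
            for _ in range(m):
                rows.append({"sample_id": f"s{i}", "subject_id": subj,
                             "timepoint": float(i), "group": "B1"})
                i += 1
        return pd.DataFrame(rows)

    def test_mad_values_and_exclusion(self):
        meta = self._meta({"p1": 6, "p2": 4})
        dist = pd.Series(
            np.r_[[1.0, 2.0, 3.0, 1.0, 2.0, 3.0], np.zeros(4)],
            index=[f"s{i}" for i in range(10)],
        )
        out = progression.subject_dispersion(meta, dist)
        assert [t.subject_id for t in out] == ["p1"]  # p2 has < 5 serial samples
        # distances 1,2,3,1,2,3: median 2, MAD 1 -> dispersion 1.5
        assert out[0].dispersion == pytest.approx(1.5)

    def test_constant_distances_zero_dispersion(self):
        meta = self._meta({"p1": 5})
        dist = pd.Series(np.full(5, 2.2), index=[f"s{i}" for i in range(5)])
        out = progression.subject_dispersion(meta, dist)
        assert out[0].dispersion == 0.0


def test_rooting_preserves_pairwise_arcs():
    tree, labels, groups = _star_model()
    model = progression.build_progression_graph(tree, labels, groups=groups)
    arcs = {(a, b): nx.shortest_path_length(model.graph, a, b, weight="raw_length")
            for a in model.graph for b in model.graph}
    paths_1 = progression.extract_paths(model, root=1)
    paths_3 = progression.extract_paths(model, root=3)
    assert len(paths_1) == 2 and len(paths_3) == 2
    arcs_after = {(a, b): nx.shortest_path_length(model.graph, a, b, weight="raw_length")
                  for a in model.graph for b in model.graph}
    assert arcs == arcs_after


def test_equalize_origin_scale():
    # two origin branches of lengths 1 and 2 joined at a junction cluster
    Z = np.array([[0.0, 1.0, 3.0, 1.0], [0.0, 0.0, 0.0, 2.0]])
    edges = [(0, 1), (1, 2), (1, 3)]
    tree = PrincipalTree(W=np.eye(2), Y=Z.copy(), Z=Z, edges=edges, P=np.eye(4),
                         sigma=0.1, gamma=2.0, lambda_tree=1.0, d=2, mean=np.zeros(2))
    labels = np.array([1, 2, 3, 4])
    groups = np.array(["HC", "B1", "B2", "HC"])
    model = progression.build_progression_graph(tree, labels, groups=groups)
    assert sorted(model.origins) == [1, 4]
    scale = progression.equalize_origin_scale(model)
    (edge, factor), = scale.items()
    short_len = model.graph.edges[edge]["raw_length"]
    other = [o for o in model.origins if o not in edge] or [o for o in model.origins if o in edge]
    # scaled short branch matches the longer origin branch
    lengths = sorted(
        model.graph.edges[o, next(iter(model.graph.neighbors(o)))]["raw_length"]
        for o in model.origins
    )
    assert short_len * factor == pytest.approx(lengths[-1])
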