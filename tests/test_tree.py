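import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import special_ortho_group, spearmanr

from microtraj.tree import (
    DDRTree,
    count_leaves,
    elbow_index,
    fit_principal_tree,
    mst_kruskal,
    projection_step,
    soft_assignments,
    tune_elbow,
)


def brute_force_mst_cost(cost):
    """Exhaustive minimum over all spanning trees (edge subsets of size n-1)."""
    n = cost.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    best = np.inf
    for subset in itertools.combinations(pairs, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            best = min(best, sum(cost[i, j] for i, j in subset))
    return best


class TestKruskal:
    def test_two_nodes(self):
        assert mst_kruskal(np.array([[0.0, 3.0], [3.0, 0.0]])) == [(0, 1)]

    def test_triangle_keeps_two_cheapest(self):
        c = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        edges = mst_kruskal(c)
        assert sorted(edges) == [(0, 1), (1, 2)]

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            c = rng.uniform(0.1, 10, size=(6, 6))
            c = (c + c.T) / 2
            np.fill_diagonal(c, 0.0)
            edges = mst_kruskal(c)
            total = sum(c[i, j] for i, j in edges)
            assert total == pytest.approx(brute_force_mst_cost(c))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            mst_kruskal(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestSoftAssignments:
    def test_equidistant_uniform(self):
        Y = np.zeros((2, 1))
        Z = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
        P = soft_assignments(Y, Z, sigma=0.7)
        np.testing.assert_allclose(P[0], 0.25)

    def test_small_sigma_concentrates(self):
        Y = np.array([[0.0], [0.0]])
        Z = np.array([[0.1, 2.0], [0.0, 0.0]])
        P = soft_assignments(Y, Z, sigma=1e-3)
        assert P[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_two_node_logistic_value(self):
        Y = np.zeros((1, 1))
        Z = np.array([[0.0, 1.0]])
        P = soft_assignments(Y, Z, sigma=1.0)
        np.testing.assert_allclose(P[0], [1 / (1 + np.e**-1), np.e**-1 / (1 + np.e**-1)],
                                   atol=1e-12)

    def test_rows_normalised(self):
        rng = np.random.default_rng(0)
        P = soft_assignments(rng.normal(size=(3, 20)), rng.normal(size=(3, 15)), 0.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)


class TestProjectionStep:
    def test_recovers_exact_subspace(self):
        rng = np.random.default_rng(1)
        basis, _ = np.linalg.qr(rng.normal(size=(10, 2)))
        scores = rng.normal(size=(2, 40)) * 3
        X = basis @ scores
        Z = np.zeros((2, 40))
        P = np.full((40, 40), 1.0 / 40)
        W, Y = projection_step(X, Z, P, gamma=1e-9)
        assert float(((X - W @ Y) ** 2).sum()) < 1e-8

    def test_identical_points_zero_objective(self):
        X = np.ones((4, 5))
        Xc = X - X.mean(axis=1, keepdims=True)  # identically zero
        Z = np.zeros((2, 5))
        P = np.full((5, 5), 0.2)
        W, Y = projection_step(Xc, Z, P, gamma=2.0)
        assert float(((Xc - W @ Y) ** 2).sum()) == pytest.approx(0.0, abs=1e-12)


class TestFit:
    def test_line_recovers_order(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 60)
        direction = rng.normal(size=10)
        direction /= np.linalg.norm(direction)
        X = np.outer(t, direction) * 5.0
        tree = fit_principal_tree(X, sigma=0.01, lambda_tree=1.0)
        assert count_leaves(tree) == 2
        y1 = tree.Y[np.argmax(tree.Y.var(axis=1))]
        assert abs(spearmanr(y1, t).statistic) >= 0.99

    def test_objective_monotone_and_tree_invariants(self, fitted_tree):
        tr = np.array(fitted_tree.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.abs(tr[:-1]))
        n = fitted_tree.Z.shape[1]
        assert len(fitted_tree.edges) == n - 1
        assert nx.is_connected(fitted_tree.graph())
        np.testing.assert_allclose(fitted_tree.W.T @ fitted_tree.W, np.eye(fitted_tree.d),
                                   atol=1e-6)
        np.testing.assert_allclose(fitted_tree.P.sum(axis=1), 1.0, atol=1e-9)

    def test_two_samples_single_edge(self):
        tree = fit_principal_tree(np.array([[0.0, 0.0], [1.0, 1.0]]),
                                  sigma=0.1, lambda_tree=1.0)
        assert tree.edges == [(0, 1)]

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6))
        R = special_ortho_group.rvs(6, random_state=1)
        t1 = fit_principal_tree(X, sigma=0.3, lambda_tree=5.0)
        t2 = fit_principal_tree(X @ R.T, sigma=0.3, lambda_tree=5.0)
        d1 = np.linalg.norm(t1.Y[:, :, None] - t1.Y[:, None, :], axis=0)
        d2 = np.linalg.norm(t2.Y[:, :, None] - t2.Y[:, None, :], axis=0)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_four_leaf_recovery_on_bifurcation(self, fitted_tree):
        assert count_leaves(fitted_tree) == 4


class TestElbow:
    def test_elbow_on_knee_curve(self):
        assert elbow_index([100.0, 20.0, 18.0, 17.0]) == 1

    def test_flat_curve_midpoint_with_warning(self):
        with pytest.warns(UserWarning):
            assert elbow_index([5.0, 5.0, 5.0, 5.0]) == 2

    def test_defaults_when_grids_omitted(self):
        assert tune_elbow(np.zeros((3, 2))) == (0.5, 150.0)


def test_estimator_transform_consistency(trajectory_transformed):
    abund, _meta, truth = trajectory_transformed
    X = abund.transformed.T[:, truth.informative][:80]
    ddr = DDRTree(sigma=0.1, lambda_tree=50.0).fit(X)
    assert ddr.embedding_.shape == (80, 3)
    # out-of-sample transform of the training data stays near the embedding
    proj = ddr.transform(X)
    assert proj.shape == (80, 3)
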