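import numpy as np
import pytest

from microtraj.logo import (
    LogoSelector,
    LogoState,
    epanechnikov,
    fit_logo,
    logo_objective,
    margin_context,
    select_features,
    solve_weight_subproblem,
    tune_lambda,
    weighted_manhattan,
)
from microtraj.synthetic import make_classification_dataset


class TestDistanceAndKernel:
    @pytest.mark.parametrize(
        "x1, x2, w, expected",
        [
            ([0, 0], [1, 2], [1, 1], 3.0),
            ([5, -1], [2, 7], [0, 0], 0.0),
            ([1, 4], [3, 1], [2, 0.5], 5.5),
        ],
    )
    def test_weighted_manhattan(self, x1, x2, w, expected):
        assert weighted_manhattan(x1, x2, w) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_manhattan([1], [1, 2], [1, 1])

    @pytest.mark.parametrize(
        "dist, bw, expected", [(0.0, 1.0, 0.75), (1.0, 1.0, 0.0), (0.5, 1.0, 0.5625)]
    )
    def test_epanechnikov_values(self, dist, bw, expected):
        assert epanechnikov(dist, bw) == pytest.approx(expected)


class TestMarginContext:
    def test_single_candidate_recovers_plain_margin(self):
        # one miss and one hit: probabilities are 1 and the expected margin
        # component equals |x - NM| - |x - NH| exactly
        X = np.array([[0.0, 0.0], [2.0, 1.0], [0.5, 0.25], [9.0, 9.0]])
        y = np.array([0, 1, 0, 1])
        ctx = margin_context(X, y, np.ones(2), k=1)
        for p in ctx.p_miss + ctx.p_hit:
            assert p.sum() == pytest.approx(1.0)
        expect = np.abs(X[0] - X[1]) - np.abs(X[0] - X[2])
        np.testing.assert_allclose(ctx.zbar[0], expect)

    def test_equidistant_misses_share_mass(self):
        X = np.array([[0.0], [1.0], [-1.0], [0.1], [0.2]])
        y = np.array([0, 1, 1, 0, 0])
        ctx = margin_context(X, y, np.ones(1), k=1)
        np.testing.assert_allclose(ctx.p_miss[0], [0.5, 0.5])

    def test_one_dim_kernel_probabilities(self):
        # misses at 1 and 2 with k=1: bandwidth 2, kernel (0.5625, 0) -> (1, 0)
        X = np.array([[0.0], [1.0], [2.0], [0.3], [0.6]])
        y = np.array([0, 1, 1, 0, 0])
        ctx = margin_context(X, y, np.ones(1), k=1)
        np.testing.assert_allclose(ctx.p_miss[0], [1.0, 0.0])

    def test_rows_sum_to_one_property(self, classification_fixture):
        X, y, _ = classification_fixture
        idx = np.r_[0:15, 50:65, 100:115]  # span all three classes
        ctx = margin_context(X[idx], y[idx], np.full(X.shape[1], 0.01), k=5)
        for p in ctx.p_miss + ctx.p_hit:
            assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestWeightSubproblem:
    def test_huge_penalty_zeroes(self):
        rng = np.random.default_rng(0)
        zbar = rng.normal(size=(30, 5))
        w, _ = solve_weight_subproblem(zbar, 1e6 * 30, np.full(5, 0.2))
        np.testing.assert_allclose(w, 0.0)

    def test_zero_zbar_gives_zero(self):
        w, _ = solve_weight_subproblem(np.zeros((10, 3)), 0.5, np.full(3, 0.3))
        np.testing.assert_allclose(w, 0.0)
        assert logo_objective(w, np.zeros((10, 3)), 0.5) == pytest.approx(10 * np.log(2))

    def test_matches_1d_grid_search(self):
        zbar = np.array([[1.0], [1.0], [2.0]])
        lam = 0.5
        grid = np.arange(0.0, 5.0, 1e-4)
        objs = [logo_objective(np.array([w]), zbar, lam) for w in grid]
        w_star = grid[int(np.argmin(objs))]
        w, _ = solve_weight_subproblem(zbar, lam, np.array([0.1]))
        assert w[0] == pytest.approx(w_star, abs=1e-3)

    def test_doubling_penalty_never_grows_l1(self):
        rng = np.random.default_rng(1)
        zbar = rng.normal(0.2, 1.0, size=(50, 8))
        norms = []
        for lam in (0.5, 1.0, 2.0, 4.0):
            w, _ = solve_weight_subproblem(zbar, lam, np.full(8, 0.1))
            norms.append(np.abs(w).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))


class TestFitLogo:
    def test_recovers_informative_features(self, classification_fixture):
        X, y, info = classification_fixture
        state = fit_logo(X, y, lam=3.0)
        top10 = np.argsort(-state.w)[:10]
        assert len(set(top10) & set(info)) >= 8

    def test_weights_nonnegative_and_trace_monotone(self, classification_fixture):
        X, y, _ = classification_fixture
        state = fit_logo(X, y, lam=1.0)
        assert np.all(state.w >= 0)
        tr = np.array(state.loss_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_huge_penalty_one_iteration(self):
        X, y, _ = make_classification_dataset(n=30, d=10, seed=0)
        state = fit_logo(X, y, lam=1e6)
        np.testing.assert_allclose(state.w, 0.0)
        assert state.converged

    def test_feature_permutation_equivariance(self):
        X, y, _ = make_classification_dataset(n=45, d=12, n_informative=3, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        w1 = fit_logo(X, y, lam=1.0).w
        w2 = fit_logo(X[:, perm], y, lam=1.0).w
        np.testing.assert_allclose(w2, w1[perm], atol=1e-8)

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            fit_logo(X, np.zeros(4), lam=1.0)


class TestSelection:
    def test_cutoff_and_ordering(self):
        state = LogoState(w=np.array([0.5, 0.0005, 0.002]), lam=1.0, k=10)
        np.testing.assert_array_equal(select_features(state), [0, 2])

    def test_zero_weights_empty(self):
        state = LogoState(w=np.zeros(4), lam=1.0, k=10)
        assert select_features(state).size == 0

    def test_zero_cutoff_returns_positives(self):
        state = LogoState(w=np.array([0.1, 0.0, 1e-9]), lam=1.0, k=10)
        np.testing.assert_array_equal(select_features(state, cutoff=0.0), [0, 2])


class TestTuneLambda:
    def test_single_grid_value(self, classification_fixture):
        X, y, _ = classification_fixture
        assert tune_lambda(X, y, grid=[0.7]) == 0.7

    def test_null_data_prefers_sparsest(self):
        X, y, _ = make_classification_dataset(n=60, d=30, shift=0.0, seed=2)
        lam = tune_lambda(X, y, grid=[0.1, 1.0, 10.0], folds=3, seed=0)
        assert lam == 10.0


class TestSelectorEstimator:
    def test_sklearn_contract(self, classification_fixture):
        X, y, info = classification_fixture
        sel = LogoSelector(l1_penalty=3.0).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape[0] == X.shape[0]
        assert Xt.shape[1] == int(sel.get_support().sum())
        assert sel.get_params()["l1_penalty"] == 3.0
        # selected indices are ordered by decreasing weight
        w = sel.weights_[sel.selected_indices_]
        assert np.all(np.diff(w) <= 0)
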