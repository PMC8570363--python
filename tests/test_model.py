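"""Cluster/feature extraction, paths, target searches, adaptive refits."""

import numpy as np
import pytest

import gecco
from gecco.affinity import build_graph
from gecco.losses import make_view
from gecco.model import (
    extract_clusters,
    extract_features,
    feature_weights_from,
    find_gamma_for_clusters,
    solve_path,
)
from gecco.solver import SolverState


def two_cluster_views(rng, n_per=5, p=3, sep=6.0):
    X = np.vstack([
        rng.normal(size=(n_per, p)),
        rng.normal(size=(n_per, p)) + sep,
    ])
    return [make_view(X, "euclidean")]


class TestExtractClusters:
    def make_state(self, V):
        return SolverState(U=[], V=[V], Lam=[])

    def test_hand_built_components(self):
        # n=5, fused edges (0,1) and (1,2): components {0,1,2},{3},{4}
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 4]])
        g = build_graph(5, edges, np.ones(4))
        V = np.ones((4, 2))
        V[0] = V[1] = 0.0
        labels = extract_clusters(self.make_state(V), g)
        np.testing.assert_array_equal(labels, [0, 0, 0, 1, 2])

    def test_all_fused_one_cluster(self):
        edges = np.array([[0, 1], [1, 2]])
        g = build_graph(3, edges, np.ones(2))
        labels = extract_clusters(self.make_state(np.zeros((2, 2))), g)
        np.testing.assert_array_equal(labels, [0, 0, 0])

    def test_nothing_fused_singletons(self):
        edges = np.array([[0, 1], [1, 2]])
        g = build_graph(3, edges, np.ones(2))
        labels = extract_clusters(self.make_state(np.ones((2, 2))), g)
        np.testing.assert_array_equal(labels, [0, 1, 2])


class TestExtractFeatures:
    def test_hand_built_shrunk_column(self, rng):
        view = make_view(rng.normal(size=(4, 3)), "euclidean")
        U = view.X.copy()
        U[:, 1] = view.center[1]  # exactly at center: unselected
        st = SolverState(U=[U], V=[], Lam=[])
        masks = extract_features(st, [view])
        np.testing.assert_array_equal(masks[0], [True, False, True])

    def test_nonsmooth_uses_split_variable(self, rng):
        view = make_view(rng.normal(size=(4, 2)), "manhattan")
        st = SolverState(U=[view.X.copy()], V=[], Lam=[])
        st.R[0] = np.zeros((4, 2))
        st.R[0][:, 1] = 1.0
        masks = extract_features(st, [view])
        np.testing.assert_array_equal(masks[0], [False, True])


class TestSearches:
    def test_gamma_search_hits_target(self, rng):
        views = two_cluster_views(rng)
        g = gecco.default_graph(views, kappa=3)
        res = find_gamma_for_clusters(views, g, 2, tol=1e-6, max_iter=20000)
        assert res.n_clusters == 2
        # the two blocks are the true groups
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1

    def test_alpha_search_hits_feature_count(self, rng):
        X = np.vstack([rng.normal(size=(5, 4)), rng.normal(size=(5, 4))])
        X[:5, 0] -= 4.0
        X[5:, 0] += 4.0  # only feature 0 informative
        views = [make_view(X, "euclidean")]
        g = gecco.default_graph(views, kappa=3)
        res = gecco.find_alpha_for_features(
            views, g, 1, gamma=0.5, tol=1e-6, max_iter=20000
        )
        assert res.n_features_selected == 1
        assert res.selected[0][0]

    def test_label_permutation_equivariance(self, rng):
        views = two_cluster_views(rng)
        g1 = gecco.default_graph(views, kappa=3)
        res1 = find_gamma_for_clusters(views, g1, 2, tol=1e-6, max_iter=20000)
        perm = rng.permutation(10)
        views_p = [make_view(views[0].X[perm], "euclidean")]
        g2 = gecco.default_graph(views_p, kappa=3)
        res2 = find_gamma_for_clusters(views_p, g2, 2, tol=1e-6, max_iter=20000)
        same1 = res1.labels[:, None] == res1.labels[None, :]
        same2 = res2.labels[:, None] == res2.labels[None, :]
        np.testing.assert_array_equal(same1[np.ix_(perm, perm)], same2)


class TestPath:
    def test_trivial_grid_point(self, rng):
        views = [make_view(rng.normal(size=(5, 2)), "manhattan")]
        g = gecco.default_graph(views, kappa=2)
        pr = solve_path(views, g, [0.0], [0.0], tol=1e-7, max_iter=10000)
        assert pr.fits[0].n_clusters == 5
        assert pr.fits[0].n_features_selected == 2

    def test_warm_path_matches_cold_fits(self, rng):
        views = two_cluster_views(rng)
        g = gecco.default_graph(views, kappa=3)
        grid = [0.05, 0.2, 0.8]
        pr = solve_path(views, g, grid, [0.0], tol=1e-8, max_iter=30000)
        for gamma, fit_warm in zip(grid, pr.fits):
            cold = gecco.fit_gecco(views, g, gamma, 0.0, tol=1e-8,
                                   max_iter=30000)
            rel = abs(fit_warm.objective - cold.objective) / (
                1 + abs(cold.objective)
            )
            assert rel < 1e-5

    def test_cluster_count_weakly_decreasing(self, rng):
        views = two_cluster_views(rng)
        g = gecco.default_graph(views, kappa=3)
        grid = np.geomspace(1e-3, 5.0, 8)
        pr = solve_path(views, g, grid, [0.0], tol=1e-6, max_iter=20000)
        ks = pr.n_clusters()
        # allow the known mild non-monotonicity of convex clustering paths
        assert ks[-1] <= ks[0]
        assert (np.diff(ks) <= 1).all()


class TestAdaptive:
    def test_feature_weight_formula(self, rng):
        view = make_view(rng.normal(size=(4, 2)), "euclidean")
        U = view.center_matrix().copy()
        U = U + 0.0
        U[:, 1] += np.array([0.495, 0.495, -0.495, -0.495])  # norm 0.99
        z = feature_weights_from([view], [U], eps=0.01)[0]
        assert z[0] == pytest.approx(100.0)  # fully shrunk: 1/eps
        assert z[1] == pytest.approx(1.0)  # ||.|| = 0.99 -> 1/(0.99+0.01)

    def test_adaptive_recovers_obvious_partition(self, rng):
        X = np.vstack([rng.normal(size=(6, 3)), rng.normal(size=(6, 3)) + 8.0])
        res = gecco.adaptive_fit(
            [make_view(X, "euclidean")], n_clusters=2, kappa=3,
            tol=1e-6, max_iter=20000,
        )
        assert res.n_clusters == 2
        assert gecco.adjusted_rand_index(res.labels,
                                         [0] * 6 + [1] * 6) == 1.0

    def test_single_view_igecco_plus_equals_gecco_plus(self, rng):
        """K=1 integrative fit is exactly the single-view fit (same code
        path, same numbers)."""
        views = two_cluster_views(rng)
        g = gecco.default_graph(views, kappa=3)
        a = gecco.fit_gecco(views, g, gamma=0.3, alpha=0.1, tol=1e-8,
                            max_iter=30000)
        b = gecco.fit_gecco([views[0]], g, gamma=0.3, alpha=0.1, tol=1e-8,
                            max_iter=30000)
        assert a.objective == pytest.approx(b.objective, rel=1e-10)
        np.testing.assert_array_equal(a.labels, b.labels)
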