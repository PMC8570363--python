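"""ADMM engines: oracle agreement, fixed points, full fusion, stability."""

import numpy as np
import pytest

import gecco
from gecco.losses import make_view
from gecco.penalties import PenaltyConfig
from gecco.solver import fit, fit_full_admm, objective
from oracle import solve_oracle, true_objective


def build(views, kappa=3):
    return gecco.default_graph(views, kappa=min(kappa, views[0].n - 1))


@pytest.fixture
def toy_views(rng):
    X1 = rng.normal(size=(6, 2))
    X2 = rng.poisson(3.0, size=(6, 2)).astype(float)
    return {
        "euclid": [make_view(X1, "euclidean")],
        "manhattan": [make_view(X1 + 1.0, "manhattan")],
        "mixed": [make_view(X1, "euclidean"), make_view(X1 + 1.0, "manhattan")],
        "poisson": [make_view(X2, "poisson_ll", weight=1.0)],
        "bernoulli": [make_view((X1 > 0).astype(float), "bernoulli_ll")],
    }


class TestUnpenalizedFixedPoints:
    def test_distance_losses_recover_data_at_zero_penalty(self, toy_views):
        for key in ("euclid", "manhattan"):
            views = toy_views[key]
            g = build(views)
            res = gecco.fit_gecco(views, g, gamma=0.0, alpha=0.0, tol=1e-8,
                                  max_iter=20000)
            np.testing.assert_allclose(res.U_hat[0], views[0].X, atol=1e-5)
            assert res.n_clusters == views[0].n

    def test_stationary_point_unmoved(self, rng):
        """Zero gradient, V = DU, alpha=0: a smooth step is a no-op."""
        view = make_view(rng.normal(size=(5, 2)), "euclidean")
        g = build([view])
        cfg = PenaltyConfig(gamma=0.0, alpha=0.0)
        from gecco.solver import SolverState, step_smooth_view

        U0 = view.X.copy()
        st = SolverState(U=[U0.copy()], V=[g.D @ U0], Lam=[np.zeros((g.n_edges, 2))])
        step_smooth_view(st, 0, view, cfg, g)
        np.testing.assert_allclose(st.U[0], U0, atol=1e-12)


class TestOracleEquivalence:
    """One-step ADMM reaches the generic convex solver's objective."""

    @pytest.mark.parametrize("key,gamma,alpha", [
        ("euclid", 0.5, 0.0),
        ("manhattan", 0.5, 0.3),
        ("mixed", 0.4, 0.2),
        ("poisson", 0.3, 0.1),
        ("mixed", 0.8, 0.0),
    ])
    def test_matches_oracle(self, toy_views, key, gamma, alpha):
        views = toy_views[key]
        g = build(views)
        res = gecco.fit_gecco(views, g, gamma=gamma, alpha=alpha, tol=1e-8,
                              max_iter=40000)
        Uo = solve_oracle(views, g, gamma, alpha)
        fo = true_objective(views, g, gamma, alpha, U=Uo)
        ff = true_objective(views, g, gamma, alpha, U=res.U_hat)
        assert ff <= fo + 1e-4 * (1 + abs(fo))

    def test_full_admm_agrees_with_one_step(self, toy_views):
        for key, gamma, alpha in [("euclid", 0.5, 0.2), ("manhattan", 0.4, 0.1),
                                  ("mixed", 0.3, 0.2)]:
            views = toy_views[key]
            g = build(views)
            cfg = PenaltyConfig(gamma=gamma, alpha=alpha)
            one = fit(views, g, cfg, tol=1e-8, max_iter=40000)
            full = fit_full_admm(views, g, cfg, tol=1e-7, max_iter=2000)
            rel = abs(one.objective - full.objective) / (1 + abs(full.objective))
            assert rel < 1e-4


class TestFullFusion:
    """With a connected graph and huge gamma (or alpha), every centroid sits
    at the loss-specific center."""

    @pytest.mark.parametrize("key", ["euclid", "poisson", "bernoulli"])
    def test_gamma_fusion_smooth(self, toy_views, key):
        views = toy_views[key]
        g = build(views, kappa=views[0].n - 1)
        res = gecco.fit_gecco(views, g, gamma=1e5, alpha=0.0, tol=1e-9,
                              max_iter=50000)
        assert res.n_clusters == 1
        np.testing.assert_allclose(
            res.U_hat[0], views[0].center_matrix(), atol=1e-5
        )

    def test_gamma_fusion_manhattan_odd_n(self, rng):
        # odd n so the columnwise median (the center) is unique
        view = make_view(rng.normal(size=(5, 2)), "manhattan")
        g = build([view], kappa=4)
        res = gecco.fit_gecco([view], g, gamma=1e5, alpha=0.0, tol=1e-9,
                              max_iter=50000)
        assert res.n_clusters == 1
        np.testing.assert_allclose(
            res.U_hat[0], view.center_matrix(), atol=1e-4
        )

    def test_alpha_shrinks_all_features(self, toy_views):
        views = toy_views["mixed"]
        g = build(views)
        res = gecco.fit_gecco(views, g, gamma=1e-3, alpha=1e5, tol=1e-8,
                              max_iter=30000)
        assert res.n_features_selected == 0


class TestGlobalSolutionStability:
    def test_random_restarts_share_objective(self, toy_views, rng):
        views = toy_views["mixed"]
        g = build(views)
        cfg = PenaltyConfig(gamma=0.3, alpha=0.1)
        objs = []
        from gecco.solver import _init_state

        for trial in range(3):
            warm = _init_state(views, g, 1.0, None)
            for u in warm.U:
                u += rng.normal(scale=2.0, size=u.shape)
            st = fit(views, g, cfg, tol=1e-9, max_iter=60000, warm_start=warm)
            objs.append(st.objective)
        assert (max(objs) - min(objs)) / (1 + abs(min(objs))) < 1e-6


class TestContinuity:
    def test_solution_drift_shrinks_with_perturbation(self, toy_views):
        """The solution path has no jumps: shrinking the gamma perturbation
        shrinks the solution change proportionally."""
        views = toy_views["euclid"]
        g = build(views)
        a = gecco.fit_gecco(views, g, gamma=0.30, alpha=0.0, tol=1e-8,
                            max_iter=30000)
        denom = np.linalg.norm(np.hstack(a.U_hat))

        def drift(g2):
            b = gecco.fit_gecco(views, g, gamma=g2, alpha=0.0, tol=1e-8,
                                max_iter=30000)
            return np.linalg.norm(np.hstack(a.U_hat) - np.hstack(b.U_hat))

        d_big, d_small = drift(0.303), drift(0.3003)
        assert d_big < 0.15 * denom
        assert d_small < 0.3 * d_big + 1e-9


def test_divergence_guard(rng):
    view = make_view(rng.normal(size=(4, 2)), "manhattan")
    g = build([view])
    cfg = PenaltyConfig(gamma=0.1)
    st = fit([view], g, cfg, tol=1e-6, max_iter=2000)
    assert np.all(np.isfinite(st.U[0]))


def test_gamma_without_edges_rejected(rng):
    view = make_view(rng.normal(size=(4, 2)), "euclidean")
    from gecco.affinity import build_graph

    empty = build_graph(4, np.empty((0, 2)), np.empty(0))
    with pytest.raises(ValueError, match="graph"):
        fit([view], empty, PenaltyConfig(gamma=1.0))
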