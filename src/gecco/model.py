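"""User-facing estimation layer.

Wraps the ADMM engines into fits, regularization paths with warm starts,
searches for tuning levels that hit a requested number of clusters or
features, and the adaptive two-stage procedure that re-weights features and
fusion weights from an initial fit.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .affinity import (
    FusionGraph,
    gower_distance,
    kernel_weights,
    view_distance,
    weighted_gower_update,
)
from .losses import ViewData, make_view
from .penalties import PenaltyConfig
from .solver import SolverState, fit as solver_fit, objective

__all__ = [
    "FitResult",
    "PathResult",
    "extract_clusters",
    "extract_features",
    "fit_gecco",
    "solve_path",
    "find_gamma_for_clusters",
    "find_alpha_for_features",
    "adaptive_fit",
    "default_graph",
]


@dataclass
class FitResult:
    """A fitted clustering: centroids, labels, selected features."""

    U_hat: list[np.ndarray]
    labels: np.ndarray
    selected: list[np.ndarray]
    objective: float
    n_clusters: int
    n_features_selected: int
    converged: bool
    gamma: float
    alpha: float
    state: SolverState = field(repr=False, default=None)


@dataclass
class PathResult:
    grid: list[tuple[float, float]]  # (gamma, alpha) per point
    fits: list[FitResult]

    def n_clusters(self) -> np.ndarray:
        return np.array([f.n_clusters for f in self.fits])

    def n_features(self) -> np.ndarray:
        return np.array([f.n_features_selected for f in self.fits])


def _relabel_by_first_member(comp: np.ndarray) -> np.ndarray:
    """Deterministic labels: component containing the smallest unseen sample
    index gets the next label."""
    labels = np.empty_like(comp)
    mapping: dict[int, int] = {}
    for i, c in enumerate(comp):
        if c not in mapping:
            mapping[c] = len(mapping)
        labels[i] = mapping[c]
    return labels


def extract_clusters(
    state: SolverState, graph: FusionGraph, tol: float = 1e-7
) -> np.ndarray:
    """Cluster labels from the fusion variable.

    Samples i, i' share a cluster iff they are connected through edges whose
    fused difference ``||V_l.||_2`` is (numerically) zero; the block
    soft-threshold produces exact zeros, so ``tol`` only guards round-off.
    """
    n = graph.n
    if graph.n_edges == 0:
        return np.arange(n)
    Vcat = np.hstack(state.V)
    norms = np.linalg.norm(Vcat, axis=1)
    scale = max(1.0, norms.max())
    keep = norms <= tol * scale
    e = graph.edges[keep]
    adj = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    return _relabel_by_first_member(comp)


def extract_features(
    state: SolverState, views: list[ViewData], tol: float = 1e-7
) -> list[np.ndarray]:
    """Per-view boolean masks of selected (not fully shrunk) features.

    For a non-smooth view the feature split variable ``R`` carries exact
    zeros from its prox; for smooth views the centroid columns themselves are
    set exactly to the center by the shifted prox.
    """
    masks = []
    for k, v in enumerate(views):
        if k in state.R:
            dev = state.R[k]
        else:
            dev = state.U[k] - v.center_matrix()
        norms = np.linalg.norm(dev, axis=0)
        scale = max(1.0, norms.max())
        masks.append(norms > tol * scale)
    return masks


def default_graph(
    views: list[ViewData],
    kappa: int = 5,
    phi: float | None = None,
    scheme: str = "gaussian",
    distance: str | np.ndarray = "auto",
) -> FusionGraph:
    """Fusion graph from the data: Gower distance across views (or the
    single view's loss-based distance), kNN mask, kernel weights."""
    if isinstance(distance, np.ndarray):
        Dmat = distance
    elif distance == "gower" or (distance == "auto" and len(views) > 1):
        Dmat = gower_distance(views)
    elif distance in ("auto", "loss"):
        Dmat = view_distance(views[0])
    else:
        raise ValueError(f"unknown distance {distance!r}")
    graph = kernel_weights(Dmat, kappa=kappa, phi=phi, scheme=scheme,
                           warn_disconnected=False)
    # normalize to max weight 1: a pure reparametrization of gamma that keeps
    # the useful gamma range O(1) regardless of weight scheme
    graph.weights = graph.weights / graph.weights.max()
    return graph


def _as_views(views) -> list[ViewData]:
    out = []
    for v in views:
        if isinstance(v, ViewData):
            out.append(v)
        else:
            X, loss = v
            out.append(make_view(X, loss))
    return out


def fit_gecco(
    views,
    graph: FusionGraph,
    gamma: float,
    alpha: float = 0.0,
    zeta: Optional[list[np.ndarray]] = None,
    rho: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 10000,
    warm_start: Optional[SolverState] = None,
    over_relax: float = 1.0,
) -> FitResult:
    """Fit at one (gamma, alpha) point and extract clusters and features."""
    views = _as_views(views)
    cfg = PenaltyConfig(gamma=gamma, alpha=alpha, zeta=zeta or [])
    state = solver_fit(views, graph, cfg, rho=rho, tol=tol,
                       max_iter=max_iter, warm_start=warm_start,
                       over_relax=over_relax)
    labels = extract_clusters(state, graph)
    selected = extract_features(state, views)
    return FitResult(
        U_hat=[u.copy() for u in state.U],
        labels=labels,
        selected=selected,
        objective=state.objective,
        n_clusters=int(labels.max()) + 1,
        n_features_selected=int(sum(m.sum() for m in selected)),
        converged=state.converged,
        gamma=gamma,
        alpha=alpha,
        state=state,
    )


def solve_path(
    views,
    graph: FusionGraph,
    gamma_grid: Sequence[float],
    alpha_grid: Sequence[float] = (0.0,),
    zeta: Optional[list[np.ndarray]] = None,
    **fit_kwargs,
) -> PathResult:
    """Fit every (gamma, alpha) grid point, warm-starting each fit from the
    previous point on the same alpha-path."""
    views = _as_views(views)
    grid, fits = [], []
    for alpha in alpha_grid:
        warm = None
        for gamma in gamma_grid:
            res = fit_gecco(views, graph, gamma, alpha, zeta=zeta,
                            warm_start=warm, **fit_kwargs)
            warm = res.state
            grid.append((gamma, alpha))
            fits.append(res)
    return PathResult(grid=grid, fits=fits)


def merge_to_target(
    labels: np.ndarray,
    target: int,
    graph: FusionGraph,
    U_hat: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Reduce a partition to exactly ``target`` clusters by absorbing the
    smallest clusters.

    Regularization paths can merge several pairs at one breakpoint, skipping
    the requested count; the literature's remedy is back-tracking with
    straggler absorption.  Each smallest cluster joins the cluster it shares
    the most fusion-weight mass with (falling back to nearest mean centroid
    when it has no cross edges).
    """
    labels = labels.copy()
    if U_hat is not None:
        C = np.hstack(U_hat)
    else:
        C = None
    while len(np.unique(labels)) > target:
        uniq, counts = np.unique(labels, return_counts=True)
        small = uniq[np.argmin(counts)]
        mass = {}
        for (l1, l2), w in zip(graph.edges, graph.weights):
            a, b = labels[l1], labels[l2]
            if a == small and b != small:
                mass[b] = mass.get(b, 0.0) + w
            elif b == small and a != small:
                mass[a] = mass.get(a, 0.0) + w
        if mass:
            dest = max(mass, key=mass.get)
        elif C is not None:
            cen = {u: C[labels == u].mean(axis=0) for u in uniq}
            dest = min(
                (u for u in uniq if u != small),
                key=lambda u: np.linalg.norm(cen[u] - cen[small]),
            )
        else:
            dest = min(u for u in uniq if u != small)
        labels[labels == small] = dest
    return _relabel_by_first_member(labels)


def partition_score(views: list[ViewData], labels: np.ndarray) -> float:
    """Within-cluster refit loss of a partition: the pi-weighted loss at the
    cluster-wise loss-specific centers.  Comparable across partitions with
    the same number of clusters (equal model size)."""
    from .losses import eval_loss

    U = refit_centroids(views, labels)
    return float(sum(v.weight * eval_loss(v.loss, v.X, u)
                     for v, u in zip(views, U)))


def find_gamma_for_clusters(
    views,
    graph: FusionGraph,
    target: int,
    alpha: float = 0.0,
    zeta=None,
    gamma0: float = 1e-3,
    max_doublings: int = 40,
    refine_steps: int = 6,
    absorb: bool = True,
    deadline: float | None = None,
    **fit_kwargs,
) -> FitResult:
    """Fit with ``target`` clusters, chosen over the fusion path.

    A warm-started forward sweep doubles gamma until the path drops to or
    past the target count, then re-sweeps the bracketing interval on a finer
    geometric grid.  Because breakpoints can merge several pairs at once
    (skipping the count) and near-breakpoint states are delicate, every
    visited partition with at least ``target`` clusters is a candidate: it
    is reduced to exactly ``target`` clusters by straggler absorption
    (:func:`merge_to_target`) and scored by its within-cluster refit loss;
    the best-scoring candidate is delivered.  This is the back-tracking
    recommended for exact-count recovery, with an explicit
    equal-model-size selection rule.  ``absorb=False`` instead returns the
    raw path point whose count is nearest the target.
    """
    views = _as_views(views)
    fk = dict(fit_kwargs)
    tol = fk.pop("tol", 1e-5)
    max_iter = fk.pop("max_iter", 10000)

    def out_of_time():
        return deadline is not None and time.monotonic() > deadline

    def do_fit(gamma, warm):
        return fit_gecco(views, graph, gamma, alpha, zeta=zeta,
                         warm_start=warm, tol=tol, max_iter=max_iter, **fk)

    from dataclasses import replace

    best = None
    best_score = np.inf
    nearest = None

    def consider(res):
        nonlocal best, best_score, nearest
        if nearest is None or abs(res.n_clusters - target) < abs(
            nearest.n_clusters - target
        ):
            nearest = res
        if res.n_clusters < target:
            return
        labels = (res.labels if res.n_clusters == target
                  else merge_to_target(res.labels, target, graph, res.U_hat))
        score = partition_score(views, labels)
        if score < best_score:
            best_score = score
            best = replace(res, labels=labels, n_clusters=target)

    warm = None
    gamma = gamma0
    lo = hi = None
    for _ in range(max_doublings):
        res = do_fit(gamma, warm)
        warm = res.state
        consider(res)
        if res.n_clusters <= target:
            hi = gamma
            break
        lo = gamma
        gamma *= 2.0
        if out_of_time():
            break
    if hi is None:
        warnings.warn("target cluster count not reached within gamma range",
                      UserWarning, stacklevel=2)
    elif lo is not None and not out_of_time():
        # finer warm-started pass through the transition region
        for gamma in np.geomspace(lo, hi, refine_steps + 2)[1:-1]:
            res = do_fit(gamma, warm)
            warm = res.state
            consider(res)
            if res.n_clusters <= 1 or out_of_time():
                break
    if not absorb or best is None:
        return nearest
    return best


def find_alpha_for_features(
    views,
    graph: FusionGraph,
    target: int,
    gamma: float,
    zeta=None,
    alpha0: float = 1e-3,
    max_doublings: int = 60,
    bisections: int = 18,
    deadline: float | None = None,
    **fit_kwargs,
) -> FitResult:
    """Alpha whose fit selects ``target`` features (pooled over views);
    doubling then bisection, nearest fit if the count is skipped."""
    views = _as_views(views)

    def better(res, cur):
        if cur is None:
            return True
        da = abs(res.n_features_selected - target)
        db = abs(cur.n_features_selected - target)
        if da != db:
            return da < db
        return (res.n_features_selected == cur.n_features_selected
                and res.alpha < cur.alpha)

    def out_of_time():
        return deadline is not None and time.monotonic() > deadline

    def rank_cut(res):
        """When the discrete alpha path skips the exact count, back-track by
        the penalty's own ordering: a column's survival margin is its fitted
        deviation norm over its weight; keep the top columns."""
        if res is None or res.n_features_selected <= target:
            return res
        margins = []
        for k, v in enumerate(views):
            z = (np.asarray(zeta[k], float) if zeta is not None
                 else np.ones(v.p))
            dev = np.linalg.norm(res.U_hat[k] - v.center_matrix(), axis=0)
            for j in range(v.p):
                if res.selected[k][j]:
                    margins.append((dev[j] / max(z[j], 1e-12), k, j))
        margins.sort(reverse=True)
        selected = [np.zeros(v.p, dtype=bool) for v in views]
        for _, k, j in margins[:target]:
            selected[k][j] = True
        from dataclasses import replace

        return replace(res, selected=selected, n_features_selected=target)

    alpha = alpha0
    warm = None
    lo = hi = None
    best = None
    first = fit_gecco(views, graph, gamma, alpha, zeta=zeta, **fit_kwargs)
    best = first
    if first.n_features_selected <= target:
        # even the first probe under-selects: walk alpha down to bracket
        hi = alpha
        warm = first.state
        for _ in range(30):
            alpha *= 0.25
            res = fit_gecco(views, graph, gamma, alpha, zeta=zeta,
                            warm_start=warm, **fit_kwargs)
            warm = res.state
            if better(res, best):
                best = res
            if res.n_features_selected > target:
                lo = alpha
                break
            hi = alpha
            if out_of_time():
                return best
    else:
        lo = alpha
        warm = first.state
        for _ in range(max_doublings):
            alpha *= 2.0
            res = fit_gecco(views, graph, gamma, alpha, zeta=zeta,
                            warm_start=warm, **fit_kwargs)
            warm = res.state
            if better(res, best):
                best = res
            if res.n_features_selected <= target:
                hi = alpha
                break
            lo = alpha
            if out_of_time():
                return rank_cut(best)
    if hi is None:
        warnings.warn("target feature count not reached within alpha range",
                      UserWarning, stacklevel=2)
        return rank_cut(best)
    if best.n_features_selected == target or lo is None:
        return rank_cut(best)
    for _ in range(2):
        grid = np.geomspace(lo, hi, bisections // 2 + 2)[1:-1]
        warm = None
        new_lo, new_hi = lo, hi
        for alpha in grid:
            if out_of_time():
                return rank_cut(best)
            res = fit_gecco(views, graph, gamma, alpha, zeta=zeta,
                            warm_start=warm, **fit_kwargs)
            warm = res.state
            if better(res, best):
                best = res
            if res.n_features_selected > target:
                new_lo = alpha
            else:
                new_hi = alpha
                break
        if best.n_features_selected == target:
            break
        lo, hi = new_lo, new_hi
    return rank_cut(best)


def feature_weights_from(
    views: list[ViewData], U_hat: list[np.ndarray], eps: float = 0.01,
    normalize: bool = False,
) -> list[np.ndarray]:
    """Adaptive feature weights ``zeta_j = 1 / (||U_.j - c_j 1||_2 + eps)``:
    features an initial fit shrank to their center get weight ~1/eps.

    With ``normalize`` the importances are first scaled to max 1 within each
    view, making the weights invariant to the overall shrinkage level of the
    initial estimate.
    """
    out = []
    for v, U in zip(views, U_hat):
        imp = np.linalg.norm(U - v.center_matrix(), axis=0)
        if normalize and imp.max() > 0:
            imp = imp / imp.max()
        out.append(1.0 / (imp + eps))
    return out


def refit_centroids(views: list[ViewData], labels: np.ndarray) -> list[np.ndarray]:
    """Unpenalized centroid refit on a partition: each sample's row is its
    cluster's loss-specific center.  Removes the shrinkage bias of the
    penalized estimate before importances are read off."""
    from .losses import loss_center

    out = []
    for v in views:
        U = np.empty_like(v.X, dtype=float)
        for c in np.unique(labels):
            rows = labels == c
            U[rows] = loss_center(v.loss, v.X[rows])
        out.append(U)
    return out


def alpha_scale(views, zeta=None, q: float = 0.5) -> float:
    """Data-driven scale for the feature penalty level.

    A column collapses to its center once ``alpha * zeta_j`` exceeds the
    loss pull on that column; at the null model the pull is the column norm
    of the weighted loss gradient (bounded by ``pi sqrt(n)`` for the
    non-differentiable distance losses).  The ``q``-quantile of those
    per-column thresholds gives an alpha at which roughly a fraction ``q``
    of the features remain active.
    """
    from .losses import grad_loss

    per_view = []
    for k, v in enumerate(views):
        z = np.ones(v.p) if zeta is None or k >= len(zeta) else zeta[k]
        if v.loss.smooth:
            G = v.weight * grad_loss(v.loss, v.X, v.center_matrix())
            g = np.linalg.norm(G, axis=0)
        else:
            # subgradient bound: the l1-type pull is (near) constant across
            # columns, so the quantile is already the collapse point
            g = np.full(v.p, v.weight * np.sqrt(v.n))
        per_view.append(np.quantile(g / np.maximum(z, 1e-12), q))
    return float(min(per_view))


def adaptive_fit(
    views,
    n_clusters: int,
    n_features: Optional[int] = None,
    kappa: int = 5,
    phi: float | None = None,
    scheme: str | None = None,
    eps: float = 0.01,
    rounds: int = 2,
    **fit_kwargs,
) -> FitResult:
    """Adaptive two-stage fit.

    1. Fit with alpha=1 and unit feature weights over gamma, taking the gamma
       that yields ``n_clusters`` clusters; this gives initial centroids.
    2. Re-weight: feature weights ``zeta_j = 1/(||U_.j - c_j 1|| + eps)`` and
       Gaussian-kernel fusion weights on the importance-weighted Gower
       distance.
    3. Refit, choosing gamma for ``n_clusters`` and (when requested) alpha
       for ``n_features`` selected features, alternating a couple of rounds.
    """
    views = _as_views(views)
    if scheme is None:
        scheme = "sne" if len(views) > 1 else "gaussian"
    graph0 = default_graph(views, kappa=kappa, phi=phi, scheme=scheme)
    # initial fit with unit feature weights at a moderate feature-penalty
    # level: a fraction of the smallest view's median collapse threshold,
    # tempering noise without degenerating any view, whatever the loss
    # scalings
    alpha_init = 0.1 * alpha_scale(views)
    init = find_gamma_for_clusters(
        views, graph0, n_clusters, alpha=alpha_init, zeta=None, **fit_kwargs
    )
    # read feature importances from the unpenalized cluster refit: at the
    # gamma reaching the oracle count the penalized centroids can be shrunk
    # almost entirely to the centers, leaving no usable signal; the refit
    # needs only the partition, so step 1's own shrinkage level is harmless
    U_imp = refit_centroids(views, init.labels)
    zeta = feature_weights_from(views, U_imp, eps=eps, normalize=True)
    degenerate = any(
        np.linalg.norm(U_imp[k] - v.center_matrix(), axis=0).max() <= 0
        for k, v in enumerate(views)
    )
    if degenerate:
        warnings.warn(
            "initial fit shrank an entire view; falling back to unit "
            "feature weights",
            UserWarning,
            stacklevel=2,
        )
        zeta = [np.ones(v.p) for v in views]
        graph = graph0
    else:
        Dhat = weighted_gower_update(views, U_imp)
        graph = kernel_weights(Dhat, kappa=kappa, phi=None, scheme="gaussian",
                               warn_disconnected=False)
        graph.weights = graph.weights / graph.weights.max()
    alpha_refit = 0.1 * alpha_scale(views, zeta)
    res = find_gamma_for_clusters(
        views, graph, n_clusters, alpha=alpha_refit, zeta=zeta, **fit_kwargs
    )
    if n_features is None:
        return res
    alpha_fit = None  # last feature-constrained fit
    for _ in range(rounds):
        cand = find_alpha_for_features(
            views, graph, n_features, gamma=res.gamma, zeta=zeta, **fit_kwargs
        )
        alpha_fit = cand
        if cand.n_clusters == n_clusters and (
            cand.n_features_selected == n_features
        ):
            return cand
        res = find_gamma_for_clusters(
            views, graph, n_clusters, alpha=cand.alpha, zeta=zeta,
            **fit_kwargs
        )
        if res.n_clusters == n_clusters:
            cand = find_alpha_for_features(
                views, graph, n_features, gamma=res.gamma, zeta=zeta,
                **fit_kwargs
            )
            alpha_fit = cand
            if cand.n_clusters == n_clusters:
                return cand
    # the two oracles never coincided in one fit: report the cluster-valid
    # labels together with the feature-constrained selection
    if alpha_fit is not None and (
        res.n_features_selected != n_features
        and alpha_fit.n_features_selected == n_features
    ):
        from dataclasses import replace

        res = replace(res, selected=alpha_fit.selected,
                      n_features_selected=alpha_fit.n_features_selected)
    return res
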