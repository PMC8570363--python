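"""End-to-end benchmark pipelines.

Thin compositions of the simulation, affinity, model and evaluation layers
that reproduce the standard experiments: integrative clustering with an
oracle cluster count, adaptive fits with oracle cluster/feature counts, and
the sparse-convex-clustering special case.  Used by the acceptance script
and the heavier tests; solver budgets are keyword-tunable.
"""

from __future__ import annotations

import time

import numpy as np

from .evaluate import adjusted_rand_index, feature_f1
from .losses import LossSpec, make_view
from .model import (
    adaptive_fit,
    default_graph,
    find_alpha_for_features,
    find_gamma_for_clusters,
)
from .simulate import SyntheticDataset, gen_multi_view, gen_single_view

#: per-view losses for the three-view benchmarks
MULTI_VIEW_LOSSES = ("euclidean", "manhattan", "bernoulli_ll")

DEFAULT_BUDGET = dict(tol=2e-5, max_iter=2500)


def multi_views(ds: SyntheticDataset, losses=MULTI_VIEW_LOSSES):
    return [make_view(X, loss) for X, loss in zip(ds.views, losses)]


def single_view(ds: SyntheticDataset, loss, weight=1.0):
    if isinstance(loss, str):
        loss = LossSpec(loss)
    return [make_view(ds.views[0], loss, weight=weight)]


def igecco_ari(ds: SyntheticDataset, n_clusters: int = 3,
               kappa: int = 5, scheme: str = "sne",
               time_cap: float = 180.0, **budget) -> float:
    """Integrative fit (no feature selection) at the oracle cluster count;
    returns the adjusted Rand index against the true labels."""
    opts = {**DEFAULT_BUDGET, **budget}
    views = multi_views(ds)
    graph = default_graph(views, kappa=kappa, scheme=scheme)
    res = find_gamma_for_clusters(views, graph, n_clusters, alpha=0.0,
                                  deadline=time.monotonic() + time_cap,
                                  **opts)
    return adjusted_rand_index(ds.labels, res.labels)


def adaptive_igecco_plus(ds: SyntheticDataset, n_clusters: int = 3,
                         n_features: int | None = None, kappa: int = 5,
                         time_cap: float = 420.0, **budget):
    """Adaptive integrative fit; returns (ARI, pooled feature F1, FitResult).

    F1 is computed only when an oracle feature count is requested.
    """
    opts = {**DEFAULT_BUDGET, **budget}
    views = multi_views(ds)
    res = adaptive_fit(views, n_clusters=n_clusters, n_features=n_features,
                       kappa=kappa, scheme="sne",
                       deadline=time.monotonic() + time_cap, **opts)
    ari = adjusted_rand_index(ds.labels, res.labels)
    f1 = (feature_f1(list(res.selected), list(ds.informative))
          if n_features is not None else float("nan"))
    return ari, f1, res


def adaptive_gecco_plus_f1(ds: SyntheticDataset, loss,
                           n_clusters: int = 3, n_features: int = 10,
                           kappa: int = 5, time_cap: float = 240.0,
                           **budget) -> float:
    """Single-view adaptive fit with oracle counts; feature-selection F1."""
    opts = {**DEFAULT_BUDGET, **budget}
    views = single_view(ds, loss)
    res = adaptive_fit(views, n_clusters=n_clusters, n_features=n_features,
                       kappa=kappa, scheme="gaussian",
                       deadline=time.monotonic() + time_cap, **opts)
    return feature_f1(res.selected[0], ds.informative[0])


def sparse_convex_clustering_f1(ds: SyntheticDataset, n_clusters: int = 3,
                                n_features: int = 10, kappa: int = 5,
                                time_cap: float = 120.0, **budget) -> float:
    """Sparse convex clustering: the Euclidean, column-centered special case
    with Euclidean-distance Gaussian kernel weights and unit feature
    weights; F1 of the alpha-level selecting the oracle feature count."""
    opts = {**DEFAULT_BUDGET, **budget}
    X = ds.views[0] - ds.views[0].mean(axis=0)
    views = [make_view(X, "euclidean", weight=1.0)]
    graph = default_graph(views, kappa=kappa, scheme="gaussian")
    dl = time.monotonic() + time_cap
    base = find_gamma_for_clusters(views, graph, n_clusters, alpha=0.0,
                                   deadline=dl, **opts)
    res = find_alpha_for_features(views, graph, n_features,
                                  gamma=base.gamma, deadline=dl, **opts)
    return feature_f1(res.selected[0], ds.informative[0])


# -- scenario -> callable registry used by the acceptance script -----------

def run_target(name: str, seed: int, **budget) -> float:
    """Compute one benchmark quantity for one seeded replicate."""
    if name == "single_s1_adaptive_f1":
        ds = gen_single_view("S1A", p_noise=215, seed=seed)
        return adaptive_gecco_plus_f1(ds, "manhattan", **budget)
    if name == "single_s2_adaptive_f1":
        ds = gen_single_view("S2", p_noise=215, seed=seed)
        return adaptive_gecco_plus_f1(ds, "manhattan", **budget)
    if name == "single_s3_adaptive_f1":
        ds = gen_single_view("S3", p_noise=215, seed=seed)
        return adaptive_gecco_plus_f1(ds, "poisson_ll", **budget)
    if name == "single_s1_sparse_cc_f1":
        ds = gen_single_view("S1A", p_noise=215, seed=seed)
        return sparse_convex_clustering_f1(ds, **budget)
    if name == "multi_s1_igecco_ari":
        return igecco_ari(gen_multi_view("S1", seed=seed), **budget)
    if name == "multi_s2_igecco_ari":
        return igecco_ari(gen_multi_view("S2", seed=seed), **budget)
    if name == "multi_s3_igecco_ari":
        return igecco_ari(gen_multi_view("S3", seed=seed), **budget)
    if name == "multi_s3_adaptive_ari":
        ari, _, _ = adaptive_igecco_plus(gen_multi_view("S3", seed=seed),
                                         **budget)
        return ari
    if name == "multi_s5_adaptive_ari_f1":
        ari, f1, _ = adaptive_igecco_plus(gen_multi_view("S5", seed=seed),
                                          n_features=30, **budget)
        return ari, f1
    raise ValueError(f"unknown benchmark {name!r}")
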