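"""Pairwise distances, kNN fusion weights and the difference-matrix graph.

Fusion weights decide which sample pairs are eligible to merge and how hard
the fusion penalty pulls on each pair.  Following standard convex-clustering
practice they are sparse (restricted to a symmetrized k-nearest-neighbour
mask) and decay with distance, either through a Gaussian kernel
``w = exp(-phi * d)`` or through symmetrized SNE conditional probabilities.
For mixed multi-view data the distance is the Gower distance; for a single
view the view's own loss supplies the metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .losses import ViewData, eval_loss, loss_center

__all__ = [
    "FusionGraph",
    "gower_distance",
    "view_distance",
    "knn_mask",
    "kernel_weights",
    "weighted_gower_update",
    "phi_from_median",
]


class DisconnectedGraphWarning(UserWarning):
    """The kNN fusion graph is not connected; full fusion cannot occur."""


@dataclass
class FusionGraph:
    """Sparse fusion-weight graph over sample pairs.

    ``edges[m] = (l1, l2)`` with ``l1 < l2`` carries weight ``weights[m] > 0``
    and the corresponding row of the signed incidence matrix ``D`` has +1 in
    column ``l1`` and -1 in column ``l2``.
    """

    n: int
    edges: np.ndarray  # (|eps|, 2) int, each row l1 < l2
    weights: np.ndarray  # (|eps|,) positive floats
    D: sparse.csr_matrix  # |eps| x n
    _Dt: sparse.csr_matrix = None  # cached transpose in csr form

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def apply_D(self, U: np.ndarray) -> np.ndarray:
        """D @ U as a row gather: rows U[l1] - U[l2]."""
        if self.n_edges == 0:
            return np.zeros((0, U.shape[1]))
        return U[self.edges[:, 0]] - U[self.edges[:, 1]]

    def apply_Dt(self, Y: np.ndarray) -> np.ndarray:
        """D.T @ Y with a cached csr transpose."""
        if self._Dt is None:
            object.__setattr__(self, "_Dt", self.D.T.tocsr())
        return self._Dt @ Y

    def is_connected(self) -> bool:
        if self.n_edges == 0:
            return self.n <= 1
        adj = sparse.coo_matrix(
            (np.ones(self.n_edges), (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n, self.n),
        )
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1

    def to_edge_list(self) -> np.ndarray:
        """(i, j, w) rows, exportable as delimited text."""
        return np.column_stack([self.edges, self.weights])


def _incidence(n: int, edges: np.ndarray) -> sparse.csr_matrix:
    m = len(edges)
    if m == 0:
        return sparse.csr_matrix((0, n))
    rows = np.repeat(np.arange(m), 2)
    cols = edges.reshape(-1)
    vals = np.tile([1.0, -1.0], m)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(m, n))


def build_graph(n: int, edges, weights) -> FusionGraph:
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    weights = np.asarray(weights, dtype=float).reshape(-1)
    if len(edges) != len(weights):
        raise ValueError("edges and weights length mismatch")
    if np.any(weights <= 0):
        raise ValueError("fusion weights must be strictly positive")
    if np.any(edges[:, 0] >= edges[:, 1]):
        raise ValueError("edges must be ordered pairs l1 < l2")
    if len({tuple(e) for e in edges}) != len(edges):
        raise ValueError("duplicate edges")
    return FusionGraph(n=n, edges=edges, weights=weights, D=_incidence(n, edges))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def gower_distance(views: list[ViewData] | list[np.ndarray]) -> np.ndarray:
    """Gower distance across views: range-normalized mean absolute difference.

    ``d(i, i') = sum_k sum_j |x_ij - x_i'j| / R_j  /  sum_k p_k`` where
    ``R_j`` is the range of feature j.  Zero-range features are dropped from
    both numerator and denominator.  Entries lie in [0, 1].
    """
    mats = [v.X if isinstance(v, ViewData) else np.atleast_2d(np.asarray(v, float))
            for v in views]
    if not mats:
        raise ValueError("need at least one view")
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ValueError("views must share the same number of rows (samples)")
    num = np.zeros((n, n))
    p_eff = 0
    for X in mats:
        rng = X.max(axis=0) - X.min(axis=0)
        keep = rng > 0
        p_eff += int(keep.sum())
        for j in np.nonzero(keep)[0]:
            num += np.abs(X[:, j][:, None] - X[:, j][None, :]) / rng[j]
    if p_eff == 0:
        return np.zeros((n, n))
    return num / p_eff


def view_distance(view: ViewData) -> np.ndarray:
    """Pairwise distance between samples using the view's own loss.

    Distance losses give the usual metric; deviance/likelihood losses are
    symmetrized as ``l(x_i, c(x_j)) + l(x_j, c(x_i))`` where ``c(x)`` maps a
    row to the loss's centroid-parameter scale.
    """
    X = view.X
    fam = view.loss.family
    if fam == "euclidean":
        return squareform(pdist(X, "euclidean"))
    if fam == "manhattan":
        return squareform(pdist(X, "cityblock"))
    if fam == "chebychev":
        return squareform(pdist(X, "chebyshev"))
    if fam == "minkowski":
        return squareform(pdist(X, "minkowski", p=view.loss.q))
    if fam == "mahalanobis":
        VI = view.loss._C_inv
        return squareform(pdist(X, "mahalanobis", VI=VI)) ** 2
    # likelihood / deviance families: symmetrized deviance between rows,
    #   d(i,j) = l(x_i, c_j) - l(x_i, c_i) + l(x_j, c_i) - l(x_j, c_j),
    # the likelihood-ratio (Bregman) form -- zero for identical rows, unlike
    # the raw cross losses which carry a self-loss baseline.  Every family
    # here has exponential-family structure a(x) + b(u) + x * c(u), so the
    # whole pairwise matrix reduces to one matrix product.
    n = X.shape[0]
    # half-count continuity clamp: a single-row center of a zero count would
    # otherwise sit at log(eps) and dominate every distance involving it
    clamp = 0.5 if fam in ("poisson_ll", "poisson_dev", "negbin_ll",
                           "negbin_dev") else None
    C = np.vstack([
        loss_center(view.loss, X[i:i + 1, :], clamp=clamp) for i in range(n)
    ])
    a, b, c = _abc_decomposition(view.loss, X, C)
    A = b.sum(axis=1)[None, :] + X @ c.T  # a(x) terms cancel in the ratio
    D = A + A.T - np.diag(A)[:, None] - np.diag(A)[None, :]
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _abc_decomposition(loss, X, C):
    """Per-element pieces of l(x, u) = a(x) + b(u) + x*c(u) evaluated at the
    data matrix X and the row-center matrix C."""
    fam = loss.family
    if fam == "poisson_ll":
        return np.zeros_like(X), np.exp(C), -C
    if fam == "bernoulli_ll":
        return np.zeros_like(X), np.logaddexp(0.0, C), -C
    if fam == "negbin_ll":
        inv = 1.0 / loss.theta_nb
        lse = np.logaddexp(np.log(inv), C)
        # -x*u + (x + 1/theta)*lse = x*(lse - u) + lse/theta
        return np.zeros_like(X), inv * lse, lse - C
    if fam == "negbin_dev":
        th = loss.theta_nb
        inv = 1.0 / th
        with np.errstate(divide="ignore", invalid="ignore"):
            xlogx = np.where(X > 0, X * np.log(X), 0.0)
        a = xlogx - (X + inv) * np.log(1.0 + th * X)
        b = inv * np.log(1.0 + th * C)
        c = np.log(1.0 + th * C) - np.log(C)
        return a, b, c
    if fam == "poisson_dev":
        with np.errstate(divide="ignore", invalid="ignore"):
            xlogx = np.where(X > 0, X * np.log(X), 0.0)
        return xlogx - X, C, -np.log(C)
    if fam == "binomial_dev":
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(X > 0, X * np.log(X), 0.0) + np.where(
                X < 1, (1 - X) * np.log(1 - X), 0.0
            )
        # x log(x/u) + (1-x) log((1-x)/(1-u))
        #   = a(x) - log(1-u) + x * (log(1-u) - log(u))
        return a, -np.log(1 - C), np.log(1 - C) - np.log(C)
    raise ValueError(f"no decomposition for {fam}")


def phi_from_median(Dmat: np.ndarray) -> float:
    """Kernel decay rate such that phi * median(off-diagonal distance) = 1."""
    n = Dmat.shape[0]
    off = Dmat[np.triu_indices(n, k=1)]
    med = np.median(off)
    return 1.0 / med if med > 0 else 0.0


# ---------------------------------------------------------------------------
# kNN mask and kernel weights
# ---------------------------------------------------------------------------

def knn_mask(Dmat: np.ndarray, kappa: int) -> np.ndarray:
    """Symmetric boolean mask: true iff j is among i's kappa nearest or vice
    versa.  Ties broken by lowest index (argsort is stable on ties)."""
    Dmat = np.asarray(Dmat, dtype=float)
    n = Dmat.shape[0]
    if Dmat.shape != (n, n) or not np.allclose(Dmat, Dmat.T):
        raise ValueError("Dmat must be a symmetric square matrix")
    if not 1 <= kappa <= n - 1:
        raise ValueError(f"kappa must be in [1, {n - 1}]")
    mask = np.zeros((n, n), dtype=bool)
    big = Dmat.copy()
    np.fill_diagonal(big, np.inf)
    order = np.argsort(big, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), kappa)
    cols = order[:, :kappa].reshape(-1)
    mask[rows, cols] = True
    return mask | mask.T


def kernel_weights(
    Dmat: np.ndarray,
    kappa: int = 5,
    phi: float | None = None,
    scheme: str = "gaussian",
    warn_disconnected: bool = True,
) -> FusionGraph:
    """Sparse fusion weights from a distance matrix.

    gaussian: ``w_ij = exp(-phi d_ij)`` on the kNN mask.
    sne: symmetrized conditional probabilities
    ``p_ij = (p_j|i + p_i|j) / (2n)`` with
    ``p_j|i = exp(-phi d_ij) / sum_{k != i} exp(-phi d_ik)``, masked.

    ``phi=None`` uses the median rule (``phi * median(d) = 1``).
    """
    Dmat = np.asarray(Dmat, dtype=float)
    n = Dmat.shape[0]
    if phi is None:
        phi = phi_from_median(Dmat)
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    mask = knn_mask(Dmat, kappa)
    if scheme == "gaussian":
        W = np.exp(-phi * Dmat)
    elif scheme == "sne":
        K = np.exp(-phi * Dmat)
        np.fill_diagonal(K, 0.0)
        P = K / K.sum(axis=1, keepdims=True)  # p_{j|i} in row i
        W = (P + P.T) / (2.0 * n)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    iu, ju = np.nonzero(np.triu(mask, k=1))
    edges = np.column_stack([iu, ju])
    weights = W[iu, ju]
    graph = build_graph(n, edges, weights)
    if warn_disconnected and not graph.is_connected():
        warnings.warn(
            "kNN fusion graph is disconnected; clusters cannot merge across "
            "components and full fusion to the loss-specific center is "
            "unattainable",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    return graph


def weighted_gower_update(
    views: list[ViewData], U_hat: list[np.ndarray]
) -> np.ndarray:
    """Feature-importance-weighted Gower distance (adaptive refit step).

    Each per-feature Gower term ``d^(k)_ii'j`` is scaled by the estimated
    importance ``||U_hat_.j - center_j||_2`` normalized to max 1 within its
    view, and by the view's inverse loss weight ``1/pi_k``.  Views whose
    features were all shrunk to their centers contribute nothing.
    """
    n = views[0].n
    out = np.zeros((n, n))
    for view, U in zip(views, U_hat):
        imp = np.linalg.norm(U - view.center_matrix(), axis=0)
        mx = imp.max()
        if mx <= 0:
            warnings.warn(
                "all features shrunk to center in one view; it contributes "
                "no distance information",
                UserWarning,
                stacklevel=2,
            )
            continue
        imp = imp / mx
        X = view.X
        rng = X.max(axis=0) - X.min(axis=0)
        for j in np.nonzero((rng > 0) & (imp > 0))[0]:
            out += (imp[j] / view.weight / rng[j]) * np.abs(
                X[:, j][:, None] - X[:, j][None, :]
            )
    return out
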