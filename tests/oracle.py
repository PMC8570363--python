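"""Independent generic convex solver used as a test oracle.

Minimizes the full clustering objective directly over the stacked centroid
variables with scipy's L-BFGS-B after smoothing every non-differentiable
norm by sqrt(x^2 + eps^2).  Shares no code with the ADMM solver: the
objective, gradients and smoothing live here.  Since
``f <= f_eps <= f + eps * (number of norm terms)``, the smoothed minimizer's
true objective brackets the optimum to O(eps * terms), far below the 1e-4
relative tolerance the comparisons use.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

EPS = 1e-9


def _snorm(A, axis, eps=EPS):
    return np.sqrt(np.sum(A * A, axis=axis) + eps * eps)


def _loss_and_grad(family, X, U, theta_nb=None, eps=EPS):
    """Smoothed loss value and gradient wrt U (elementwise families plus the
    row-coupled distance losses used in toy problems)."""
    R = X - U
    if family == "euclidean":
        return 0.5 * np.sum(R * R), -R
    if family == "manhattan":
        s = np.sqrt(R * R + eps * eps)
        return np.sum(s), -R / s
    if family == "chebychev":
        # smooth max via log-sum-exp with small temperature
        t = 1e-6
        A = np.abs(R)
        m = A.max(axis=1, keepdims=True)
        w = np.exp((A - m) / t)
        val = np.sum(m[:, 0] + t * np.log(np.sum(w, axis=1)))
        g = -np.sign(R) * w / w.sum(axis=1, keepdims=True)
        return val, g
    if family == "poisson_ll":
        return np.sum(-X * U + np.exp(U)), -X + np.exp(U)
    if family == "bernoulli_ll":
        sig = 1.0 / (1.0 + np.exp(-U))
        return np.sum(-X * U + np.logaddexp(0.0, U)), -X + sig
    if family == "poisson_dev":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(X > 0, X * np.log(X / U), 0.0)
        return np.sum(term - X + U), 1.0 - X / U
    raise ValueError(family)


def oracle_objective(views, graph, gamma, alpha, zeta=None, U=None, eps=EPS):
    """Smoothed objective and gradient at stacked centroids ``U`` (list)."""
    val = 0.0
    grads = []
    D, w = graph.D, graph.weights
    m = graph.n_edges
    diffs = (
        np.hstack([D @ u for u in U]) if m else np.zeros((0, 1))
    )
    if m:
        dn = _snorm(diffs, axis=1, eps=eps)
        val += gamma * float(w @ dn)
    off = 0
    for k, v in enumerate(views):
        u = U[k]
        lv, lg = _loss_and_grad(v.loss.family, v.X, u, v.loss.theta_nb, eps)
        val += v.weight * lv
        g = v.weight * lg
        if m and gamma > 0:
            blk = diffs[:, off:off + v.p]
            g = g + gamma * (D.T @ (blk * (w / dn)[:, None]))
        if alpha > 0:
            z = zeta[k] if zeta is not None else np.ones(v.p)
            dev = u - v.center_matrix()
            cn = _snorm(dev, axis=0, eps=eps)
            val += alpha * float(z @ cn)
            g = g + alpha * dev * (z / cn)[None, :]
        grads.append(g)
        off += v.p
    return val, grads


def solve_oracle(views, graph, gamma, alpha=0.0, zeta=None, eps=EPS,
                 maxiter=20000):
    """Minimize the smoothed objective by L-BFGS-B; returns centroid list."""
    shapes = [v.X.shape for v in views]
    sizes = [s[0] * s[1] for s in shapes]

    def unpack(x):
        out, off = [], 0
        for s, sz in zip(shapes, sizes):
            out.append(x[off:off + sz].reshape(s))
            off += sz
        return out

    def fun(x):
        U = unpack(x)
        val, grads = oracle_objective(views, graph, gamma, alpha, zeta, U, eps)
        return val, np.concatenate([g.reshape(-1) for g in grads])

    x0 = np.concatenate([v.loss.init_centroid(v.X).reshape(-1) for v in views])
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12})
    return unpack(res.x)


def true_objective(views, graph, gamma, alpha=0.0, zeta=None, U=None):
    """Unsmoothed objective, written independently of the package."""
    val = 0.0
    if graph.n_edges:
        diffs = np.hstack([graph.D @ u for u in U])
        val += gamma * float(graph.weights @ np.linalg.norm(diffs, axis=1))
    for k, v in enumerate(views):
        X, u, fam = v.X, U[k], v.loss.family
        if fam == "euclidean":
            lv = 0.5 * np.sum((X - u) ** 2)
        elif fam == "manhattan":
            lv = np.sum(np.abs(X - u))
        elif fam == "chebychev":
            lv = np.sum(np.max(np.abs(X - u), axis=1))
        elif fam == "poisson_ll":
            lv = np.sum(-X * u + np.exp(u))
        elif fam == "bernoulli_ll":
            lv = np.sum(-X * u + np.logaddexp(0.0, u))
        elif fam == "poisson_dev":
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(X > 0, X * np.log(X / u), 0.0)
            lv = np.sum(t - X + u)
        else:
            raise ValueError(fam)
        val += v.weight * lv
        if alpha > 0:
            z = zeta[k] if zeta is not None else np.ones(v.p)
            val += alpha * float(
                z @ np.linalg.norm(u - v.center_matrix(), axis=0)
            )
    return val
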