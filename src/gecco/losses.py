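"""Convex losses for generalized convex clustering.

Each loss family measures the discrepancy between a data matrix ``X`` and a
centroid matrix ``U`` of the same shape and is convex in ``U``.  Families come
in three flavours:

* distance losses (``euclidean``, ``manhattan``, ``minkowski``, ``chebychev``,
  ``mahalanobis``) of the form ``f(X - U)``;
* exponential-family negative log-likelihoods (``poisson_ll``,
  ``bernoulli_ll``, ``negbin_ll``) where ``U`` lives on the natural-parameter
  scale (log / logit of the mean);
* deviances (``poisson_dev``, ``binomial_dev``, ``negbin_dev``) where ``U``
  lives on the mean scale.  Deviances are implemented in their nonnegative
  Bregman form (zero at ``U == X``) so that the reciprocal null deviance is a
  valid positive loss weight.

Every family has a *loss-specific center*: the per-column minimizer of the
loss summed over samples (mean, median, log-mean, ...).  At full
regularization all centroids coalesce to this center, and the feature penalty
shrinks towards it; both penalties therefore agree on what "no signal" means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

__all__ = [
    "LossSpec",
    "ViewData",
    "FAMILIES",
    "eval_loss",
    "grad_loss",
    "prox_loss",
    "loss_center",
    "null_deviance_weight",
    "make_view",
]

#: recognised family names -> smoothness (smooth == gradient defined on domain)
FAMILIES = {
    "euclidean": True,
    "manhattan": False,
    "minkowski": None,  # smooth iff q > 1
    "chebychev": False,
    "mahalanobis": True,
    "poisson_ll": True,
    "poisson_dev": True,
    "bernoulli_ll": True,
    "binomial_dev": True,
    "negbin_ll": True,
    "negbin_dev": True,
}

#: loss names recognised for interoperability but not implemented (non-convex or never exercised)
UNSUPPORTED = {"hinge", "kl_divergence", "hamming", "canberra"}

_EPS = 1e-12


class UnsupportedOperationError(NotImplementedError):
    """Operation not defined for this loss family."""


class InvalidDomainError(ValueError):
    """Data or centroid values outside the loss's admissible domain."""


class DegenerateViewError(ValueError):
    """View with (numerically) zero null deviance."""


@dataclass(frozen=True)
class LossSpec:
    """A convex loss family with its parameters.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    q : float, optional
        Minkowski exponent, ``q >= 1``.
    C : ndarray, optional
        Positive-definite weighting matrix for the Mahalanobis loss.
    theta_nb : float, optional
        Negative-binomial dispersion (``> 0``); required for the negbin
        families.  (Printed elsewhere as a dispersion "alpha"; renamed to
        avoid collision with the feature tuning parameter.)
    """

    family: str
    q: Optional[float] = None
    C: Optional[np.ndarray] = None
    theta_nb: Optional[float] = None
    clamp: float = 0.02
    _C_inv: Optional[np.ndarray] = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        fam = self.family
        if fam in UNSUPPORTED:
            raise UnsupportedOperationError(
                f"loss family {fam!r} is recognised but not implemented"
            )
        if fam not in FAMILIES:
            raise ValueError(f"unknown loss family {fam!r}")
        if fam == "minkowski":
            if self.q is None or self.q < 1:
                raise ValueError("minkowski loss requires exponent q >= 1")
        if fam == "mahalanobis":
            if self.C is None:
                raise ValueError("mahalanobis loss requires a matrix C")
            C = np.asarray(self.C, dtype=float)
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError as exc:
                raise ValueError("mahalanobis C must be positive definite") from exc
            object.__setattr__(self, "C", C)
            object.__setattr__(self, "_C_inv", np.linalg.inv(C))
        if fam in ("negbin_ll", "negbin_dev"):
            if self.theta_nb is None or self.theta_nb <= 0:
                raise ValueError("negative-binomial loss requires theta_nb > 0")

    @property
    def smooth(self) -> bool:
        s = FAMILIES[self.family]
        if s is None:  # minkowski
            return self.q > 1
        return s

    @property
    def is_distance(self) -> bool:
        return self.family in (
            "euclidean",
            "manhattan",
            "minkowski",
            "chebychev",
            "mahalanobis",
        )

    # -- domain handling ---------------------------------------------------
    def check_data(self, X: np.ndarray) -> None:
        X = np.asarray(X)
        if not np.all(np.isfinite(X)):
            raise InvalidDomainError("data contains non-finite values")
        fam = self.family
        if fam in ("poisson_ll", "poisson_dev", "negbin_ll", "negbin_dev"):
            if np.any(X < 0):
                raise InvalidDomainError(f"{fam} requires nonnegative data")
        if fam in ("bernoulli_ll", "binomial_dev"):
            if np.any((X < 0) | (X > 1)):
                raise InvalidDomainError(f"{fam} requires data in [0, 1]")

    def check_centroid(self, U: np.ndarray) -> None:
        U = np.asarray(U)
        fam = self.family
        if fam in ("poisson_dev", "negbin_dev"):
            if np.any(U <= 0):
                raise InvalidDomainError(f"{fam} requires centroids > 0 (mean scale)")
        if fam == "binomial_dev":
            if np.any((U <= 0) | (U >= 1)):
                raise InvalidDomainError(
                    "binomial_dev requires centroids in (0, 1) (mean scale)"
                )

    def init_centroid(self, X: np.ndarray) -> np.ndarray:
        """A feasible, well-scaled starting centroid matrix for ``X``."""
        X = np.asarray(X, dtype=float)
        fam = self.family
        c = self.clamp
        if fam in ("poisson_ll", "negbin_ll"):
            return np.log(X + 0.5)
        if fam == "bernoulli_ll":
            p = np.clip(X, c, 1 - c)
            return np.log(p / (1 - p))
        if fam in ("poisson_dev", "negbin_dev"):
            return X + 0.5
        if fam == "binomial_dev":
            return np.clip(X, c, 1 - c)
        return X.copy()

    def domain_box(self) -> tuple[float, float]:
        """Convex box the centroid iterates are kept in.

        Boundary-seeking losses on degenerate data (0/1 observations under
        the Bernoulli families, zero counts under the Poisson deviance) have
        unbounded or boundary-singular minimizers; clamping at ``clamp``
        (mean scale) -- equivalently capping natural parameters at the
        clamped logit -- keeps the problem well-posed.  Returns
        (-inf, inf) for unconstrained families.
        """
        fam = self.family
        c = self.clamp
        if fam == "binomial_dev":
            return (c, 1.0 - c)
        if fam == "bernoulli_ll":
            cap = np.log((1.0 - c) / c)
            return (-cap, cap)
        if fam in ("poisson_dev", "negbin_dev"):
            return (c, np.inf)
        return (-np.inf, np.inf)


def _xlogxu(x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """x * log(x / u) with the convention 0 * log 0 == 0."""
    out = np.zeros(np.broadcast_shapes(x.shape, u.shape))
    pos = x > 0
    xb, ub = np.broadcast_arrays(x, u)
    out[pos] = xb[pos] * np.log(xb[pos] / ub[pos])
    return out


def eval_loss(loss: LossSpec, X: np.ndarray, U: np.ndarray) -> float:
    """Total loss ``sum_i l(X_i., U_i.)`` for the given family."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if X.shape != U.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs U {U.shape}")
    loss.check_data(X)
    loss.check_centroid(U)
    fam = loss.family
    R = X - U
    if fam == "euclidean":
        return 0.5 * float(np.sum(R * R))
    if fam == "manhattan":
        return float(np.sum(np.abs(R)))
    if fam == "minkowski":
        return float(np.sum(np.linalg.norm(R, ord=loss.q, axis=1)))
    if fam == "chebychev":
        return float(np.sum(np.max(np.abs(R), axis=1)))
    if fam == "mahalanobis":
        return float(np.sum((R @ loss._C_inv) * R))
    if fam == "poisson_ll":
        return float(np.sum(-X * U + np.exp(U)))
    if fam == "poisson_dev":
        return float(np.sum(_xlogxu(X, U) - X + U))
    if fam == "bernoulli_ll":
        # -x*u + log(1+e^u), computed stably
        return float(np.sum(-X * U + np.logaddexp(0.0, U)))
    if fam == "binomial_dev":
        return float(np.sum(_xlogxu(X, U) + _xlogxu(1.0 - X, 1.0 - U)))
    if fam == "negbin_ll":
        inv = 1.0 / loss.theta_nb
        return float(np.sum(-X * U + (X + inv) * np.logaddexp(np.log(inv), U)))
    if fam == "negbin_dev":
        th = loss.theta_nb
        inv = 1.0 / th
        return float(
            np.sum(_xlogxu(X, U) - (X + inv) * np.log((1.0 + th * X) / (1.0 + th * U)))
        )
    raise UnsupportedOperationError(fam)


def grad_loss(loss: LossSpec, X: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Elementwise gradient of :func:`eval_loss` with respect to ``U``."""
    if not loss.smooth:
        raise UnsupportedOperationError(
            f"{loss.family} is not differentiable everywhere"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if X.shape != U.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs U {U.shape}")
    loss.check_centroid(U)
    fam = loss.family
    if fam == "euclidean":
        return U - X
    if fam == "mahalanobis":
        return 2.0 * (U - X) @ loss._C_inv
    if fam == "minkowski":
        R = X - U
        q = loss.q
        norms = np.linalg.norm(R, ord=q, axis=1, keepdims=True)
        safe = np.maximum(norms, _EPS)
        return -np.sign(R) * (np.abs(R) / safe) ** (q - 1.0)
    if fam == "poisson_ll":
        return -X + np.exp(U)
    if fam == "poisson_dev":
        return 1.0 - X / U
    if fam == "bernoulli_ll":
        return -X + 1.0 / (1.0 + np.exp(-U))
    if fam == "binomial_dev":
        return (1.0 - X) / (1.0 - U) - X / U
    if fam == "negbin_ll":
        inv = 1.0 / loss.theta_nb
        eu = np.exp(U)
        return -X + (X + inv) * eu / (inv + eu)
    if fam == "negbin_dev":
        th = loss.theta_nb
        return -X / U + (X + 1.0 / th) * th / (1.0 + th * U)
    raise UnsupportedOperationError(fam)


# ---------------------------------------------------------------------------
# proximal operators for non-smooth distance losses, f(Z) acting on Z = X - U
# ---------------------------------------------------------------------------

def _project_l1_ball(a: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of vector ``a`` onto the l1 ball of ``radius``."""
    if np.sum(np.abs(a)) <= radius:
        return a.copy()
    u = np.sort(np.abs(a))[::-1]
    css = np.cumsum(u)
    k = np.nonzero(u * np.arange(1, len(a) + 1) > (css - radius))[0][-1]
    tau = (css[k] - radius) / (k + 1.0)
    return np.sign(a) * np.maximum(np.abs(a) - tau, 0.0)


def prox_loss(loss: LossSpec, A: np.ndarray, t: float) -> np.ndarray:
    """``argmin_Z 0.5 ||A - Z||_F^2 + t * f(Z)`` for distance losses ``f``.

    ``f`` is the loss applied to the residual: elementwise soft-threshold for
    manhattan, a row-wise l1-ball projection (Moreau decomposition) for
    chebychev, and a per-row numerical minimization for general minkowski.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    fam = loss.family
    if fam == "manhattan" or (fam == "minkowski" and loss.q == 1):
        return np.sign(A) * np.maximum(np.abs(A) - t, 0.0)
    if fam == "chebychev":
        if t == 0:
            return A.copy()
        out = np.empty_like(A)
        for i in range(A.shape[0]):
            out[i] = A[i] - t * _project_l1_ball(A[i] / t, 1.0)
        return out
    if fam == "minkowski":
        if t == 0:
            return A.copy()
        q = loss.q
        out = np.empty_like(A)
        for i in range(A.shape[0]):
            a = A[i]

            def obj(z, a=a):
                return 0.5 * np.sum((a - z) ** 2) + t * np.linalg.norm(z, ord=q)

            res = optimize.minimize(obj, a, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 20000})
            out[i] = res.x
        return out
    raise UnsupportedOperationError(
        f"prox_loss is defined for non-smooth distance losses, not {fam}"
    )


# ---------------------------------------------------------------------------
# loss-specific centers
# ---------------------------------------------------------------------------

def _numeric_center_1d(loss: LossSpec, col: np.ndarray) -> float:
    lo, hi = float(np.min(col)), float(np.max(col))
    if hi - lo < _EPS:
        return lo
    res = optimize.minimize_scalar(
        lambda u: eval_loss(loss, col[:, None], np.full((len(col), 1), u)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def loss_center(loss: LossSpec, X: np.ndarray, clamp: float | None = None) -> np.ndarray:
    """Columnwise loss-specific center of ``X``.

    mean (euclidean and every deviance), median (manhattan), ``log(mean)``
    (poisson_ll / negbin_ll), ``logit(mean)`` (bernoulli_ll).  Families with
    no closed form (minkowski, chebychev) are minimized numerically per
    column; the mahalanobis center is the mean (exact for the quadratic form
    when C is diagonal, and used generally since the quadratic's gradient
    vanishes at the mean).

    Degenerate log/logit arguments (zero or boundary means) are clamped to
    ``clamp`` with a warning raised as ``DegenerateViewError`` when the whole
    column is degenerate is *not* signalled here -- callers check deviances.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise ValueError("empty data matrix")
    loss.check_data(X)
    if clamp is None:
        clamp = loss.clamp if loss.family in (
            "bernoulli_ll", "binomial_dev", "poisson_dev", "negbin_dev"
        ) else 1e-6
    fam = loss.family
    xbar = X.mean(axis=0)
    if fam in ("euclidean", "mahalanobis", "poisson_dev", "negbin_dev", "binomial_dev"):
        if fam == "binomial_dev":
            return np.clip(xbar, clamp, 1.0 - clamp)
        if fam in ("poisson_dev", "negbin_dev"):
            return np.maximum(xbar, clamp)
        return xbar
    if fam == "manhattan":
        return np.median(X, axis=0)
    if fam in ("poisson_ll", "negbin_ll"):
        return np.log(np.maximum(xbar, clamp))
    if fam == "bernoulli_ll":
        p = np.clip(xbar, clamp, 1.0 - clamp)
        return np.log(p / (1.0 - p))
    if fam in ("minkowski", "chebychev"):
        # the row norms couple features; a per-row norm's center is still
        # found columnwise only when p == 1, otherwise minimize jointly by
        # coordinate descent over columns
        n, p = X.shape
        u = np.median(X, axis=0)
        if p == 1:
            u[0] = _numeric_center_1d(loss, X[:, 0])
            return u
        for _ in range(50):
            u_old = u.copy()
            for j in range(p):
                U = np.tile(u, (n, 1))

                def obj(v, j=j, U=U):
                    U[:, j] = v
                    return eval_loss(loss, X, U)

                lo, hi = X[:, j].min(), X[:, j].max()
                if hi - lo < _EPS:
                    u[j] = lo
                    continue
                res = optimize.minimize_scalar(obj, bounds=(lo, hi),
                                               method="bounded",
                                               options={"xatol": 1e-8})
                u[j] = float(res.x)
            if np.max(np.abs(u - u_old)) < 1e-8:
                break
        return u
    raise UnsupportedOperationError(fam)


# ---------------------------------------------------------------------------
# views
# ---------------------------------------------------------------------------

@dataclass
class ViewData:
    """One data view: samples-by-features matrix, its loss, center, weight."""

    X: np.ndarray
    loss: LossSpec
    center: np.ndarray
    weight: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def center_matrix(self) -> np.ndarray:
        """Center broadcast to the shape of X (the null model)."""
        return np.broadcast_to(self.center, self.X.shape)


def null_deviance_weight(view_or_loss, X: np.ndarray = None,
                         center: np.ndarray = None, tol: float = 1e-10) -> float:
    """Reciprocal null deviance ``1 / l(X, X_tilde)`` of a view.

    The null deviance is the loss at the loss-specific center broadcast to
    every row; its reciprocal puts heterogeneous losses on a common scale.
    """
    if isinstance(view_or_loss, ViewData):
        loss, X, center = view_or_loss.loss, view_or_loss.X, view_or_loss.center
    else:
        loss = view_or_loss
        if center is None:
            center = loss_center(loss, X)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    dev = eval_loss(loss, X, np.broadcast_to(np.asarray(center, float), X.shape))
    if not np.isfinite(dev) or dev <= tol:
        raise DegenerateViewError(
            f"null deviance {dev:.3g} is not positive; view is degenerate "
            "(constant columns?) or the loss is unsuitable for pi-weighting"
        )
    return 1.0 / dev


def make_view(X: np.ndarray, loss, weight: Optional[float] = None) -> ViewData:
    """Build a :class:`ViewData` with its center and (optionally) pi-weight.

    ``loss`` may be a family name or a :class:`LossSpec`.  When ``weight`` is
    None it is set to the reciprocal null deviance.
    """
    if isinstance(loss, str):
        loss = LossSpec(loss)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    loss.check_data(X)
    center = loss_center(loss, X)
    if weight is None:
        weight = null_deviance_weight(loss, X, center)
    if weight <= 0:
        raise ValueError("view weight pi must be positive")
    return ViewData(X=X, loss=loss, center=center, weight=float(weight))
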