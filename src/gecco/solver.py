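"""Multi-block ADMM engines for integrative convex clustering.

The optimization problem over per-view centroid matrices ``U^(k)`` is

    sum_k pi_k l_k(X^(k), U^(k))
      + gamma sum_l w_l || [D U^(1) ... D U^(K)]_l. ||_2
      + alpha sum_k sum_j zeta_j^(k) || U_.j^(k) - c_j^(k) 1 ||_2

with ``D`` the signed incidence matrix of the fusion graph and ``c`` the
loss-specific centers.  The joint fusion term is the l2 norm of the
*concatenated* row difference across views, so all views share one cluster
structure.

Two engines are provided:

* :func:`fit` -- the production algorithm: one inexact proximal step per view
  per outer iteration (a proximal-linearized update for differentiable
  losses, one sweep of a four-variable splitting for non-differentiable
  distance losses), followed by the closed-form fusion-variable update and
  dual ascent.  Being a convex problem, the inexact scheme reaches the same
  global objective as an exact solve.
* :func:`fit_full_admm` -- the slow reference: each view sub-problem is
  solved to inner tolerance before the fusion update.  Used as an oracle in
  tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

from .affinity import FusionGraph
from .losses import ViewData, eval_loss, grad_loss, prox_loss
from .penalties import PenaltyConfig, prox_row_groups, prox_shifted_cols

__all__ = ["SolverState", "fit", "fit_full_admm", "objective"]

_STEP_MIN = 1e-14


class StepSizeCollapseError(RuntimeError):
    pass


@dataclass
class SolverState:
    """All ADMM variables plus diagnostics.

    ``U[k]`` (n x p_k) are centroids; ``V[k]`` (|eps| x p_k) fusion slack
    with scaled duals ``Lam[k]``; non-smooth views additionally carry
    residual splits ``Z`` (loss side), ``R`` (feature-penalty side) and their
    duals ``Psi``, ``N``.
    """

    U: list[np.ndarray]
    V: list[np.ndarray]
    Lam: list[np.ndarray]
    Z: dict[int, np.ndarray] = field(default_factory=dict)
    Psi: dict[int, np.ndarray] = field(default_factory=dict)
    R: dict[int, np.ndarray] = field(default_factory=dict)
    N: dict[int, np.ndarray] = field(default_factory=dict)
    steps: dict[int, np.ndarray] = field(default_factory=dict)
    rho: float = 1.0
    iter: int = 0
    primal_res: float = np.inf
    dual_res: float = np.inf
    converged: bool = False
    objective: float = np.nan

    def copy(self) -> "SolverState":
        return SolverState(
            U=[u.copy() for u in self.U],
            V=[v.copy() for v in self.V],
            Lam=[l.copy() for l in self.Lam],
            Z={k: z.copy() for k, z in self.Z.items()},
            Psi={k: p.copy() for k, p in self.Psi.items()},
            R={k: r.copy() for k, r in self.R.items()},
            N={k: n.copy() for k, n in self.N.items()},
            steps={k: s.copy() for k, s in self.steps.items()},
            rho=self.rho,
            iter=self.iter,
            primal_res=self.primal_res,
            dual_res=self.dual_res,
            converged=self.converged,
            objective=self.objective,
        )


def objective(
    views: list[ViewData], graph: FusionGraph, cfg: PenaltyConfig, U: list[np.ndarray]
) -> float:
    """Value of the iGecco+ objective at centroids ``U``."""
    val = sum(v.weight * eval_loss(v.loss, v.X, u) for v, u in zip(views, U))
    if graph.n_edges and cfg.gamma > 0:
        diffs = np.hstack([graph.D @ u for u in U])
        val += cfg.gamma * float(graph.weights @ np.linalg.norm(diffs, axis=1))
    if cfg.alpha > 0:
        for k, (v, u) in enumerate(zip(views, U)):
            zeta = cfg.zeta_for(k, v.p)
            val += cfg.alpha * float(
                zeta @ np.linalg.norm(u - v.center_matrix(), axis=0)
            )
    return val


# ---------------------------------------------------------------------------
# per-column smooth loss values (for backtracking)
# ---------------------------------------------------------------------------

def _colwise_loss(view: ViewData, U: np.ndarray) -> np.ndarray:
    """Per-column loss sums for elementwise smooth families; +inf columns on
    domain violations (so backtracking rejects infeasible steps)."""
    X, fam = view.X, view.loss.family
    with np.errstate(all="ignore"):
        if fam == "euclidean":
            E = 0.5 * (X - U) ** 2
        elif fam == "poisson_ll":
            E = -X * U + np.exp(U)
        elif fam == "bernoulli_ll":
            E = -X * U + np.logaddexp(0.0, U)
        elif fam == "negbin_ll":
            inv = 1.0 / view.loss.theta_nb
            E = -X * U + (X + inv) * np.logaddexp(np.log(inv), U)
        elif fam == "poisson_dev":
            E = np.where(X > 0, X * np.log(np.maximum(X, 1e-300) / U), 0.0) - X + U
            E = np.where(U > 0, E, np.inf)
        elif fam == "binomial_dev":
            E = np.where(X > 0, X * np.log(np.maximum(X, 1e-300) / U), 0.0)
            E += np.where(X < 1, (1 - X) * np.log(np.maximum(1 - X, 1e-300) / (1 - U)), 0.0)
            E = np.where((U > 0) & (U < 1), E, np.inf)
        elif fam == "negbin_dev":
            th = view.loss.theta_nb
            E = np.where(X > 0, X * np.log(np.maximum(X, 1e-300) / U), 0.0)
            E -= (X + 1.0 / th) * np.log((1.0 + th * X) / (1.0 + th * U))
            E = np.where(U > 0, E, np.inf)
        elif fam == "mahalanobis":
            R = X - U
            return np.array([float(np.sum((R @ view.loss._C_inv) * R))])
        else:
            raise ValueError(fam)
    E = np.where(np.isnan(E), np.inf, E)
    return E.sum(axis=0)


def _grad_penalized(view, U, Vk, Lamk, graph, rho):
    g = view.weight * grad_loss(view.loss, view.X, U)
    if graph.n_edges:
        g = g + rho * graph.apply_Dt(graph.apply_D(U) - Vk + Lamk)
    return g


def _quad_cols(view, U, Vk, Lamk, graph, rho) -> np.ndarray:
    """Per-column value of the smooth majorized part
    pi*l + rho/2 ||D U - V + Lam||^2 (column-separable)."""
    h = view.weight * _colwise_loss(view, U)
    if graph.n_edges:
        Q = graph.apply_D(U) - Vk + Lamk
        pen = 0.5 * rho * np.sum(Q * Q, axis=0)
        if h.shape == pen.shape:
            h = h + pen
        else:  # mahalanobis: scalar
            h = h + pen.sum()
    return h


def step_smooth_view(
    state: SolverState,
    k: int,
    view: ViewData,
    cfg: PenaltyConfig,
    graph: FusionGraph,
    max_backtracks: int = 60,
) -> None:
    """One proximal-gradient step (with cached per-column backtracking) on
    view ``k``.  Mutates ``state`` in place."""
    rho = state.rho
    U = state.U[k]
    Vk, Lamk = state.V[k], state.Lam[k]
    zeta = cfg.zeta_for(k, view.p)
    # share D U between the gradient and the majorization value at U
    g = view.weight * grad_loss(view.loss, view.X, U)
    h0 = view.weight * _colwise_loss(view, U)
    if graph.n_edges:
        Q = graph.apply_D(U) - Vk + Lamk
        g = g + rho * graph.apply_Dt(Q)
        pen = 0.5 * rho * np.sum(Q * Q, axis=0)
        h0 = h0 + (pen if h0.shape == pen.shape else pen.sum())
    s = state.steps.get(k)
    scalar_step = view.loss.family == "mahalanobis"
    if s is None:
        s = np.ones(1 if scalar_step else view.p)
    else:
        s = s.copy()  # cached per-column steps, kept monotone for stability
    lo, hi = view.loss.domain_box()
    for _ in range(max_backtracks):
        step = s if scalar_step else s[None, :]
        cand = prox_shifted_cols(U - step * g, view.center, s * cfg.alpha * zeta)
        if np.isfinite(lo) or np.isfinite(hi):
            # projected proximal step: boundary-seeking losses are kept in
            # the convex domain box
            np.clip(cand, lo, hi, out=cand)
        diff = cand - U
        h1 = _quad_cols(view, cand, Vk, Lamk, graph, rho)
        if scalar_step:
            lin = float(np.sum(g * diff)) + float(np.sum(diff * diff)) / (2 * s[0])
            ok = np.array([h1[0] <= h0[0] + lin + 1e-12 * max(1.0, abs(h0[0]))])
        else:
            lin = np.sum(g * diff, axis=0) + np.sum(diff * diff, axis=0) / (2 * s)
            ok = h1 <= h0 + lin + 1e-12 * np.maximum(1.0, np.abs(h0))
        if ok.all():
            break
        s = np.where(ok, s, s * 0.5)
        if np.any(s < _STEP_MIN):
            raise StepSizeCollapseError(
                f"backtracking step collapsed below {_STEP_MIN} on view {k}"
            )
    state.steps[k] = s
    state.U[k] = cand


def step_nonsmooth_view(
    state: SolverState,
    k: int,
    view: ViewData,
    cfg: PenaltyConfig,
    graph: FusionGraph,
    M_chol,
) -> None:
    """One sweep of the four-variable splitting for a distance loss
    ``f(X - U)``: linear solve for U with M = (D'D + 2I)^-1, prox of f for Z,
    feature-penalty prox for R, then dual ascent on Psi and N."""
    rho = state.rho
    X = view.X
    Xt = view.center_matrix()
    Z, Psi = state.Z[k], state.Psi[k]
    R, N = state.R[k], state.N[k]
    zeta = cfg.zeta_for(k, view.p)
    rhs = Xt + R - N + X - Z + Psi
    if graph.n_edges:
        rhs = rhs + graph.apply_Dt(state.V[k] - state.Lam[k])
    U = cho_solve(M_chol, rhs)
    Z = prox_loss(view.loss, X - U + Psi, view.weight / rho)
    R = prox_row_groups((U - Xt + N).T, cfg.alpha * zeta / rho).T
    Psi = Psi + (X - U - Z)
    N = N + (U - Xt - R)
    state.U[k], state.Z[k], state.Psi[k] = U, Z, Psi
    state.R[k], state.N[k] = R, N
    if not np.all(np.isfinite(U)):
        raise FloatingPointError(
            "non-finite centroid update (divergence); try a different rho"
        )


def _update_fusion(state: SolverState, views, cfg, graph, over_relax: float = 1.0):
    """Shared V (block soft-threshold) and Lambda updates.

    Returns the dual-residual contribution rho*||D'(V_new - V_old)||_F."""
    if not graph.n_edges:
        return 0.0, []
    rho = state.rho
    DUs = [graph.apply_D(u) for u in state.U]
    if over_relax != 1.0:
        # standard ADMM over-relaxation on the consensus variable
        DUr = [over_relax * du + (1.0 - over_relax) * v
               for du, v in zip(DUs, state.V)]
    else:
        DUr = DUs
    A = np.hstack([du + lam for du, lam in zip(DUr, state.Lam)])
    Vnew = prox_row_groups(A, cfg.gamma * graph.weights / rho)
    dual = 0.0
    off = 0
    for k, v in enumerate(views):
        blk = Vnew[:, off:off + v.p]
        dual += float(np.sum(graph.apply_Dt(blk - state.V[k]) ** 2))
        state.V[k] = blk
        state.Lam[k] = state.Lam[k] + (DUr[k] - blk)
        off += v.p
    return rho * np.sqrt(dual), DUs


def _residuals(state: SolverState, views, graph, DUs=None) -> tuple[float, float]:
    prim = 0.0
    scale = 1.0
    for k, v in enumerate(views):
        if graph.n_edges:
            DU = DUs[k] if DUs else graph.apply_D(state.U[k])
            prim += float(np.sum((DU - state.V[k]) ** 2))
            scale = max(scale, np.linalg.norm(DU), np.linalg.norm(state.V[k]))
        if k in state.Z:
            prim += float(np.sum((v.X - state.U[k] - state.Z[k]) ** 2))
            prim += float(
                np.sum((state.U[k] - v.center_matrix() - state.R[k]) ** 2)
            )
            scale = max(scale, np.linalg.norm(v.X))
    return np.sqrt(prim), scale


def _init_state(views, graph, rho, warm_start) -> SolverState:
    if warm_start is not None:
        st = warm_start.copy()
        st.iter = 0
        st.converged = False
        st.rho = rho
        return st
    m = graph.n_edges
    U = [v.loss.init_centroid(v.X) for v in views]
    V = [np.zeros((m, v.p)) for v in views]
    Lam = [np.zeros((m, v.p)) for v in views]
    st = SolverState(U=U, V=V, Lam=Lam, rho=rho)
    for k, v in enumerate(views):
        if graph.n_edges:
            st.V[k] = graph.apply_D(U[k])
        if not v.loss.smooth:
            st.Z[k] = v.X - U[k]
            st.Psi[k] = np.zeros_like(v.X)
            st.R[k] = U[k] - v.center_matrix()
            st.N[k] = np.zeros_like(v.X)
    return st


def _M_cholesky(graph: FusionGraph):
    n = graph.n
    A = 2.0 * np.eye(n)
    if graph.n_edges:
        A += (graph.D.T @ graph.D).toarray()
    return cho_factor(A)


def _rescale_rho(state: SolverState, factor: float, rho_min=1e-2, rho_max=1e2):
    """Residual balancing: scale rho and compensate the scaled duals."""
    new = float(np.clip(state.rho * factor, rho_min, rho_max))
    if new == state.rho:
        return
    ratio = state.rho / new
    state.Lam = [l * ratio for l in state.Lam]
    for k in state.Psi:
        state.Psi[k] *= ratio
        state.N[k] *= ratio
    # cached curvature estimates change with rho; let backtracking re-settle
    state.steps = {}
    state.rho = new


def fit(
    views: list[ViewData],
    graph: FusionGraph,
    cfg: PenaltyConfig,
    rho: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 10000,
    warm_start: SolverState | None = None,
    adapt_rho: bool = True,
    over_relax: float = 1.0,
) -> SolverState:
    """Run the one-step inexact multi-block ADMM to tolerance.

    Convergence is declared when the relative primal feasibility residual and
    the relative dual residual both fall below ``tol``.  The returned state
    carries the residuals and final objective; non-convergence is flagged on
    ``state.converged`` with a warning rather than an exception.  With
    ``adapt_rho`` the augmented-Lagrangian parameter is rebalanced every few
    iterations so neither residual stalls.
    """
    if graph.n_edges == 0 and cfg.gamma > 0:
        raise ValueError("gamma > 0 requires a nonempty fusion graph")
    state = _init_state(views, graph, rho if warm_start is None else
                        warm_start.rho, warm_start)
    need_M = any(not v.loss.smooth for v in views)
    M_chol = _M_cholesky(graph) if need_M else None
    u_scale = max(1.0, *(np.linalg.norm(u) for u in state.U))
    for it in range(1, max_iter + 1):
        gm_sq = 0.0
        dual_extra = 0.0
        if it % 50 == 0:
            # periodic step regrowth: cached monotone steps tuned during the
            # stiff early phase would otherwise throttle the flat consensus
            # directions; backtracking re-shrinks them where needed
            for k in state.steps:
                state.steps[k] = np.minimum(state.steps[k] * 2.0, 1e4)
        for k, v in enumerate(views):
            Uo = state.U[k]
            if v.loss.smooth:
                step_smooth_view(state, k, v, cfg, graph)
                # gradient-mapping norm: step displacement divided by the
                # step size; unlike the raw displacement it does not vanish
                # just because the step is small
                s = state.steps[k]
                gm_sq += float(np.sum(((state.U[k] - Uo) / s) ** 2))
            else:
                Zo, Ro = state.Z[k], state.R[k]
                step_nonsmooth_view(state, k, v, cfg, graph, M_chol)
                dual_extra += float(np.sum((state.Z[k] - Zo) ** 2))
                dual_extra += float(np.sum((state.R[k] - Ro) ** 2))
                gm_sq += float(np.sum((state.U[k] - Uo) ** 2))
        dual, DUs = _update_fusion(state, views, cfg, graph, over_relax)
        dual = np.sqrt(dual**2 + (state.rho**2) * dual_extra)
        prim, scale = _residuals(state, views, graph, DUs)
        state.iter = it
        state.primal_res = prim / scale
        state.dual_res = dual / scale
        # the fusion residuals can vanish while U still slides along the
        # fused consensus direction (null space of D); require the proximal
        # update map itself to be (nearly) a fixed point as well
        stationary = np.sqrt(gm_sq) / u_scale
        if state.primal_res < tol and state.dual_res < tol and stationary < tol:
            state.converged = True
            break
        if adapt_rho and it % 5 == 0:
            if state.primal_res > 10.0 * state.dual_res and state.primal_res > tol:
                _rescale_rho(state, 2.0)
            elif state.dual_res > 10.0 * state.primal_res and state.dual_res > tol:
                _rescale_rho(state, 0.5)
            elif (state.primal_res < tol and state.dual_res < tol
                  and stationary > tol and state.rho > rho):
                # feasible but still sliding: smaller rho lengthens the
                # admissible proximal steps along the consensus direction
                _rescale_rho(state, 0.5)
    if not state.converged:
        warnings.warn(
            f"solver stopped at max_iter={max_iter} with residuals "
            f"({state.primal_res:.2e}, {state.dual_res:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    state.objective = objective(views, graph, cfg, state.U)
    return state


def fit_full_admm(
    views: list[ViewData],
    graph: FusionGraph,
    cfg: PenaltyConfig,
    rho: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 2000,
    inner_tol: float = 1e-7,
    inner_max_iter: int = 500,
) -> SolverState:
    """Reference multi-block ADMM solving each view sub-problem to inner
    tolerance (iterated proximal gradient, or iterated splitting sweeps)
    before every fusion update.  Slow; used as the oracle for :func:`fit`."""
    if graph.n_edges == 0 and cfg.gamma > 0:
        raise ValueError("gamma > 0 requires a nonempty fusion graph")
    state = _init_state(views, graph, rho, None)
    need_M = any(not v.loss.smooth for v in views)
    M_chol = _M_cholesky(graph) if need_M else None
    for it in range(1, max_iter + 1):
        for k, v in enumerate(views):
            for _ in range(inner_max_iter):
                Uo = state.U[k]
                if v.loss.smooth:
                    step_smooth_view(state, k, v, cfg, graph)
                    delta = np.linalg.norm(state.U[k] - Uo)
                    if delta < inner_tol * (1 + np.linalg.norm(Uo)):
                        break
                else:
                    step_nonsmooth_view(state, k, v, cfg, graph, M_chol)
                    r1 = np.linalg.norm(v.X - state.U[k] - state.Z[k])
                    r2 = np.linalg.norm(
                        state.U[k] - v.center_matrix() - state.R[k]
                    )
                    if max(r1, r2) < inner_tol * (1 + np.linalg.norm(v.X)):
                        break
        dual, DUs = _update_fusion(state, views, cfg, graph)
        prim, scale = _residuals(state, views, graph, DUs)
        state.iter = it
        state.primal_res = prim / scale
        state.dual_res = dual / scale
        if state.primal_res < tol and state.dual_res < tol:
            state.converged = True
            break
    if not state.converged:
        warnings.warn(
            f"full ADMM stopped at max_iter={max_iter}",
            RuntimeWarning,
            stacklevel=2,
        )
    state.objective = objective(views, graph, cfg, state.U)
    return state
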