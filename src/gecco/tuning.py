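"""Data-driven selection of (gamma, alpha) over a solved path.

The criterion is a BIC-style variant standard in convex-clustering /
group-lasso practice: twice the weighted loss plus ``log(n)`` times an
effective degrees of freedom, where df counts (distinct cluster centroids) x
(selected features pooled over views).  A subsample/co-clustering stability
scaffold is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import ViewData, eval_loss
from .model import PathResult, fit_gecco

__all__ = ["SelectionResult", "bic_select", "stability_cocluster"]


@dataclass
class SelectionResult:
    gamma: float
    alpha: float
    index: int
    criterion: np.ndarray  # per grid point
    df: np.ndarray  # per grid point


def bic_select(path: PathResult, views: list[ViewData]) -> SelectionResult:
    """Pick the grid point minimizing ``2 sum_k pi_k l_k + log(n) df``."""
    if not path.fits:
        raise ValueError("empty path")
    n = views[0].n
    crits, dfs = [], []
    for res in path.fits:
        fit_term = 2.0 * sum(
            v.weight * eval_loss(v.loss, v.X, u)
            for v, u in zip(views, res.U_hat)
        )
        df = res.n_clusters * max(res.n_features_selected, 1)
        crits.append(fit_term + np.log(n) * df)
        dfs.append(df)
    crits = np.asarray(crits)
    idx = int(np.argmin(crits))
    g, a = path.grid[idx]
    return SelectionResult(gamma=g, alpha=a, index=idx,
                           criterion=crits, df=np.asarray(dfs))


def stability_cocluster(
    views,
    graph_builder,
    gamma: float,
    alpha: float = 0.0,
    n_subsamples: int = 20,
    frac: float = 0.8,
    seed: int = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Subsample-and-count co-clustering frequencies (stability scaffold).

    Refits on random subsamples and returns the n x n matrix of empirical
    co-clustering probabilities among pairs observed together.  Intended for
    exploratory stability checks, not as a tuned selector.
    """
    from .losses import make_view

    base = [v if isinstance(v, ViewData) else make_view(*v) for v in views]
    n = base[0].n
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    seen = np.zeros((n, n))
    m = int(round(frac * n))
    for _ in range(n_subsamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = [make_view(v.X[idx], v.loss) for v in base]
        graph = graph_builder(sub)
        res = fit_gecco(sub, graph, gamma=gamma, alpha=alpha, **fit_kwargs)
        same = res.labels[:, None] == res.labels[None, :]
        co[np.ix_(idx, idx)] += same
        seen[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        return np.where(seen > 0, co / seen, np.nan)
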