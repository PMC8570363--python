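"""Proximal operators for the two structured penalties.

P1 (row fusion): ``gamma * sum_l w_l ||V_l.||_2`` on stacked row differences,
whose prox is a row-wise block soft-threshold.  Exact zero rows are what fuse
samples into clusters.

P2 (shifted feature group lasso): ``alpha * sum_j zeta_j ||U_.j - c_j 1||_2``,
whose prox block-soft-thresholds each centered column and shifts it back.
Columns collapsed exactly to their loss-specific center are the unselected
features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PenaltyConfig", "prox_row_groups", "prox_shifted_cols"]


@dataclass
class PenaltyConfig:
    """Penalty levels and feature weights.

    gamma >= 0 scales the fusion penalty (number of clusters); alpha >= 0
    scales the feature penalty (number of selected features); ``zeta`` holds
    one nonnegative weight vector per view.
    """

    gamma: float
    alpha: float = 0.0
    zeta: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.gamma < 0 or self.alpha < 0:
            raise ValueError("gamma and alpha must be nonnegative")
        self.zeta = [np.asarray(z, dtype=float) for z in self.zeta]
        for z in self.zeta:
            if np.any(z < 0):
                raise ValueError("feature weights zeta must be nonnegative")

    def zeta_for(self, k: int, p_k: int) -> np.ndarray:
        if k < len(self.zeta):
            z = self.zeta[k]
            if len(z) != p_k:
                raise ValueError("zeta length does not match view width")
            return z
        return np.ones(p_k)


def prox_row_groups(A: np.ndarray, t: np.ndarray | float) -> np.ndarray:
    """Row-wise block soft-threshold: row a -> max(0, 1 - t/||a||) a."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    t = np.broadcast_to(np.asarray(t, dtype=float), (A.shape[0],))
    if np.any(t < 0):
        raise ValueError("thresholds must be nonnegative")
    norms = np.linalg.norm(A, axis=1)
    scale = np.zeros_like(norms)
    pos = norms > t
    scale[pos] = 1.0 - t[pos] / norms[pos]
    return A * scale[:, None]


def prox_shifted_cols(
    U: np.ndarray, centers: np.ndarray, t: np.ndarray | float
) -> np.ndarray:
    """Column-wise block soft-threshold towards per-column centers.

    Column j maps to ``c_j + max(0, 1 - t_j/||u_j - c_j 1||) (u_j - c_j 1)``;
    columns within ``t_j`` of their center collapse to it exactly.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    centers = np.asarray(centers, dtype=float).reshape(-1)
    if centers.shape[0] != U.shape[1]:
        raise ValueError("centers length must equal number of columns")
    shifted = U - centers[None, :]
    out = prox_row_groups(shifted.T, t).T
    return out + centers[None, :]
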