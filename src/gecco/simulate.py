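"""Synthetic benchmark generators.

All scenarios share the same skeleton: n = 120 samples in 3 balanced clusters
of 40, with exactly the first 10 features of each view informative and the
rest noise.  Single-view scenarios add 5% high-variance outliers per cluster;
multi-view scenarios couple a continuous, a count and a binary/proportion
view through shared cluster structure (and, for the half-moon family, a
shared rank-preserving copula transform of the moon coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SyntheticDataset", "gen_single_view", "gen_multi_view",
           "three_half_moons"]

N_SAMPLES = 120
N_CLUSTERS = 3
N_INFORMATIVE = 10
OUTLIER_FRAC = 0.05

_MU_GAUSS = np.array(
    [
        [-2.5] * 5 + [0.0] * 5,
        [0.0] * 5 + [2.5] * 5,
        [2.5] * 5 + [0.0] * 5,
    ]
)
_MU_POISSON_SINGLE = np.array([1.0, 4.0, 7.0])
_MU_POISSON_MULTI = np.array([2.0, 4.0, 6.0])
_MU_BERNOULLI = np.array([0.5, 0.2, 0.8])

#: multi-view dimensions (p1, p2, p3) per scenario
MULTI_DIMS = {
    "S1": (10, 10, 10),
    "S2": (10, 10, 10),
    "S3": (200, 100, 50),
    "S4": (50, 200, 100),
    "S5": (200, 100, 50),
    "S6": (50, 200, 100),
}
#: scenarios whose informative structure is the three half moons
MULTI_MOONS = {"S2", "S5", "S6"}


@dataclass
class SyntheticDataset:
    views: list[np.ndarray]
    labels: np.ndarray
    informative: list[np.ndarray]
    scenario: str
    seed: int
    outliers: np.ndarray | None = None  # boolean rows flagged as outliers

    @property
    def n(self) -> int:
        return len(self.labels)


def _balanced_labels(n: int = N_SAMPLES) -> np.ndarray:
    per = n // N_CLUSTERS
    return np.repeat(np.arange(N_CLUSTERS), per)


def _outlier_rows(labels: np.ndarray, rng) -> np.ndarray:
    """Exactly 5% (rounded) of each cluster, chosen at random."""
    flag = np.zeros(len(labels), dtype=bool)
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        m = int(round(OUTLIER_FRAC * len(idx)))
        flag[rng.choice(idx, size=m, replace=False)] = True
    return flag


def three_half_moons(
    labels: np.ndarray,
    rng,
    noise_sd: float = 0.15,
    radius: float = 1.0,
) -> np.ndarray:
    """(n, 2) coordinates of three interlocking half moons.

    Arcs of ``radius`` with alternating orientation and offsets chosen so
    the moons interlock: upper arcs at x-offsets 0 and 3 radii, a lower arc
    between them shifted up by half a radius.  Additive Gaussian noise
    ``noise_sd`` (absolute units, not scaled by the radius).
    """
    n = len(labels)
    theta = rng.uniform(0.0, np.pi, size=n)
    centers = radius * np.array([[0.0, 0.0], [1.5, 0.5], [3.0, 0.0]])
    sign = np.array([1.0, -1.0, 1.0])
    xy = np.empty((n, 2))
    xy[:, 0] = centers[labels, 0] + radius * np.cos(theta)
    xy[:, 1] = centers[labels, 1] + sign[labels] * radius * np.sin(theta)
    return xy + rng.normal(scale=noise_sd, size=(n, 2))


def _moon_matrix(labels, rng, n_pairs: int, noise_sd: float,
                 outliers: np.ndarray | None = None,
                 outlier_sd: float = 1.0, radius: float = 1.0) -> np.ndarray:
    cols = []
    for _ in range(n_pairs):
        xy = three_half_moons(labels, rng, noise_sd=noise_sd, radius=radius)
        cols.append(xy)
    M = np.hstack(cols)
    if outliers is not None and outliers.any():
        M[outliers] += rng.normal(scale=outlier_sd,
                                  size=(outliers.sum(), M.shape[1]))
    return M


def _copula(M: np.ndarray, quantile) -> np.ndarray:
    """Rank-preserving transform of each column through ``quantile``:
    empirical CDF (mid-ranks) then the target quantile function."""
    n = M.shape[0]
    out = np.empty_like(M)
    for j in range(M.shape[1]):
        ranks = stats.rankdata(M[:, j], method="average")
        u = (ranks - 0.5) / n
        out[:, j] = quantile(u)
    return out


def gen_single_view(
    scenario: str,
    p_noise: int = 215,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Single-view benchmarks.

    S1A/S1B/S1C: spherical Gaussian clusters N(mu_k, I_10) with 5% outliers
    per cluster from N(mu_k, 25 I_10); noise features N(0, noise_sd^2).
    S2: three interlocking half moons across 5 feature pairs, 5% outliers,
    Gaussian noise features.  S3: Poisson counts with class means 1/4/7 and
    noise features Poisson with random integer means 1..10.
    """
    if p_noise < 0:
        raise ValueError("p_noise must be nonnegative")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels()
    n = len(labels)
    scenario = scenario.upper()
    outliers = None
    if scenario in ("S1", "S1A", "S1B", "S1C"):
        outliers = _outlier_rows(labels, rng)
        sd = np.where(outliers, 5.0, 1.0)[:, None]
        info = _MU_GAUSS[labels] + rng.normal(size=(n, N_INFORMATIVE)) * sd
        noise = rng.normal(scale=noise_sd, size=(n, p_noise))
    elif scenario == "S2":
        outliers = _outlier_rows(labels, rng)
        # moon radius chosen so the informative-feature variance matches the
        # spherical scenario's (class-mean spread well above the unit-noise
        # features); the arcs' shape is unit-free
        info = _moon_matrix(labels, rng, N_INFORMATIVE // 2, noise_sd=0.3,
                            outliers=outliers, outlier_sd=1.0, radius=2.0)
        noise = rng.normal(scale=noise_sd, size=(n, p_noise))
    elif scenario == "S3":
        mu = _MU_POISSON_SINGLE[labels][:, None] * np.ones(N_INFORMATIVE)
        info = rng.poisson(mu).astype(float)
        mus = rng.integers(1, 11, size=p_noise)
        noise = rng.poisson(mus, size=(n, p_noise)).astype(float)
    else:
        raise ValueError(f"unknown single-view scenario {scenario!r}")
    X = np.hstack([info, noise])
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[:N_INFORMATIVE] = True
    return SyntheticDataset(
        views=[X], labels=labels, informative=[mask],
        scenario=scenario, seed=seed, outliers=outliers,
    )


def _spherical_views(labels, rng, dims) -> list[np.ndarray]:
    n = len(labels)
    views = []
    # Gaussian view
    p = dims[0]
    info = _MU_GAUSS[labels] + rng.normal(scale=np.sqrt(3.0),
                                          size=(n, N_INFORMATIVE))
    noise = rng.normal(size=(n, p - N_INFORMATIVE))
    views.append(np.hstack([info, noise]))
    # Poisson view
    p = dims[1]
    mu = _MU_POISSON_MULTI[labels][:, None] * np.ones(N_INFORMATIVE)
    info = rng.poisson(mu).astype(float)
    mus = rng.integers(1, 11, size=p - N_INFORMATIVE)
    noise = rng.poisson(mus, size=(n, p - N_INFORMATIVE)).astype(float)
    views.append(np.hstack([info, noise]))
    # Bernoulli view
    p = dims[2]
    prob = _MU_BERNOULLI[labels][:, None] * np.ones(N_INFORMATIVE)
    info = rng.binomial(1, prob).astype(float)
    ps = rng.uniform(0.1, 0.9, size=p - N_INFORMATIVE)
    noise = rng.binomial(1, ps, size=(n, p - N_INFORMATIVE)).astype(float)
    views.append(np.hstack([info, noise]))
    return views


def _moon_views(labels, rng, dims) -> list[np.ndarray]:
    n = len(labels)
    views = []
    count_q = lambda u: stats.poisson.ppf(u, mu=4.0)
    prop_q = lambda u: stats.beta.ppf(u, 2.0, 2.0)
    # continuous view, larger noise than the single-view moons
    p = dims[0]
    info = _moon_matrix(labels, rng, N_INFORMATIVE // 2, noise_sd=0.25)
    noise = rng.normal(size=(n, p - N_INFORMATIVE))
    views.append(np.hstack([info, noise]))
    # count view: copula transform of fresh moon coordinates
    p = dims[1]
    info = _copula(_moon_matrix(labels, rng, N_INFORMATIVE // 2, 0.25), count_q)
    noise = rng.poisson(4.0, size=(n, p - N_INFORMATIVE)).astype(float)
    views.append(np.hstack([info, noise]))
    # proportion view
    p = dims[2]
    info = _copula(_moon_matrix(labels, rng, N_INFORMATIVE // 2, 0.25), prop_q)
    noise = rng.beta(2.0, 2.0, size=(n, p - N_INFORMATIVE))
    views.append(np.hstack([info, noise]))
    return views


def gen_multi_view(scenario: str, seed: int = 0) -> SyntheticDataset:
    """Three-view benchmarks (continuous / count / binary-or-proportion).

    Spherical scenarios (S1, S3, S4): Gaussian N(mu_k, 3 I), Poisson means
    2/4/6, Bernoulli means 0.5/0.2/0.8.  Half-moon scenarios (S2, S5, S6):
    moon geometry in the continuous view and rank-preserving copula
    transforms (Poisson(4) counts, Beta(2,2) proportions) in the others.
    Dimensions per scenario follow :data:`MULTI_DIMS`.
    """
    scenario = scenario.upper()
    if scenario not in MULTI_DIMS:
        raise ValueError(f"unknown multi-view scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    labels = _balanced_labels()
    dims = MULTI_DIMS[scenario]
    if scenario in MULTI_MOONS:
        views = _moon_views(labels, rng, dims)
    else:
        views = _spherical_views(labels, rng, dims)
    informative = []
    for p in dims:
        m = np.zeros(p, dtype=bool)
        m[:N_INFORMATIVE] = True
        informative.append(m)
    return SyntheticDataset(
        views=views, labels=labels, informative=informative,
        scenario=scenario, seed=seed,
    )


#: default per-view losses for the multi-view benchmarks
MULTI_LOSSES = ["euclidean", "manhattan", "bernoulli_ll"]
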