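"""Loss families: values, gradients, proxes, centers, null-deviance weights."""

import numpy as np
import pytest

from gecco.losses import (
    DegenerateViewError,
    InvalidDomainError,
    LossSpec,
    UnsupportedOperationError,
    eval_loss,
    grad_loss,
    loss_center,
    make_view,
    null_deviance_weight,
    prox_loss,
)

SMOOTH = ["euclidean", "mahalanobis", "poisson_ll", "poisson_dev",
          "bernoulli_ll", "binomial_dev", "negbin_ll", "negbin_dev"]
NONSMOOTH = ["manhattan", "chebychev"]


def spec_for(family):
    kw = {}
    if family == "mahalanobis":
        kw["C"] = np.array([[2.0, 0.3], [0.3, 1.0]])
    if family == "minkowski":
        kw["q"] = 3.0
    if family.startswith("negbin"):
        kw["theta_nb"] = 0.5
    return LossSpec(family, **kw)


def admissible_xu(family, rng, n=5, p=2):
    """Random (X, U) pair inside the family's domain."""
    if family in ("poisson_ll", "poisson_dev", "negbin_ll", "negbin_dev"):
        X = rng.poisson(3.0, size=(n, p)).astype(float)
        U = rng.uniform(0.5, 5.0, size=(n, p))
        if family.endswith("_ll"):
            U = np.log(U)
        return X, U
    if family in ("bernoulli_ll", "binomial_dev"):
        X = rng.uniform(0.05, 0.95, size=(n, p))
        U = rng.uniform(0.1, 0.9, size=(n, p))
        if family == "bernoulli_ll":
            U = np.log(U / (1 - U))
        return X, U
    X = rng.normal(size=(n, p))
    U = rng.normal(size=(n, p))
    return X, U


@pytest.mark.parametrize(
    "family,x,u,expected",
    [
        ("manhattan", [[1.0, 2.0]], [[0.0, 0.0]], 3.0),
        ("poisson_ll", [[1.0]], [[0.0]], 1.0),  # -x*u + e^u = 0 + 1
        ("euclidean", [[1.5, -2.0]], [[1.5, -2.0]], 0.0),
        ("chebychev", [[1.0, -3.0]], [[0.0, 0.0]], 3.0),
        ("poisson_dev", [[2.0]], [[2.0]], 0.0),  # Bregman form is 0 at X==U
        ("binomial_dev", [[0.0]], [[0.5]], np.log(2.0)),
    ],
)
def test_eval_loss_hand_values(family, x, u, expected):
    assert eval_loss(spec_for(family), np.array(x), np.array(u)) == pytest.approx(
        expected, abs=1e-12
    )


def test_eval_loss_shape_and_domain_errors():
    with pytest.raises(ValueError, match="shape"):
        eval_loss(spec_for("euclidean"), np.zeros((2, 2)), np.zeros((3, 2)))
    with pytest.raises(InvalidDomainError):
        eval_loss(spec_for("binomial_dev"), np.array([[0.5]]), np.array([[1.5]]))
    with pytest.raises(InvalidDomainError):
        eval_loss(spec_for("poisson_dev"), np.array([[-1.0]]), np.array([[1.0]]))


@pytest.mark.parametrize("family", SMOOTH + NONSMOOTH + ["minkowski"])
def test_convexity_in_u(family, rng):
    """l(x, .) is convex along random segments in the admissible domain."""
    spec = spec_for(family)
    for _ in range(10):
        X, U1 = admissible_xu(family, rng)
        _, U2 = admissible_xu(family, rng)
        lam = rng.uniform()
        mid = eval_loss(spec, X, lam * U1 + (1 - lam) * U2)
        bound = lam * eval_loss(spec, X, U1) + (1 - lam) * eval_loss(spec, X, U2)
        assert mid <= bound + 1e-9 * (1 + abs(bound))


@pytest.mark.parametrize("family", SMOOTH)
def test_grad_matches_finite_differences(family, rng):
    spec = spec_for(family)
    X, U = admissible_xu(family, rng)
    G = grad_loss(spec, X, U)
    h = 1e-6
    for idx in [(0, 0), (2, 1), (4, 0)]:
        Up, Um = U.copy(), U.copy()
        Up[idx] += h
        Um[idx] -= h
        fd = (eval_loss(spec, X, Up) - eval_loss(spec, X, Um)) / (2 * h)
        assert G[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)


@pytest.mark.parametrize(
    "x,u,expected",
    [(1.0, 0.0, 0.0), (0.5, 0.0, 0.0)],
)
def test_grad_hand_values(x, u, expected):
    # poisson_ll at x=1, u=0: -1 + e^0 = 0 ; bernoulli_ll at x=.5, u=0
    fam = "poisson_ll" if x == 1.0 else "bernoulli_ll"
    g = grad_loss(spec_for(fam), np.array([[x]]), np.array([[u]]))
    assert g[0, 0] == pytest.approx(expected, abs=1e-12)


def test_grad_on_nonsmooth_family_raises():
    with pytest.raises(UnsupportedOperationError):
        grad_loss(spec_for("manhattan"), np.zeros((2, 2)), np.zeros((2, 2)))


class TestProx:
    def test_manhattan_soft_threshold(self):
        spec = spec_for("manhattan")
        assert prox_loss(spec, np.array([[3.0]]), 1.0)[0, 0] == pytest.approx(2.0)
        assert prox_loss(spec, np.array([[0.5]]), 1.0)[0, 0] == pytest.approx(0.0)

    def test_zero_penalty_is_identity(self, rng):
        A = rng.normal(size=(4, 3))
        for fam in NONSMOOTH:
            np.testing.assert_allclose(prox_loss(spec_for(fam), A, 0.0), A)

    @pytest.mark.parametrize("family", NONSMOOTH)
    def test_prox_optimality(self, family, rng):
        """prox output beats nearby perturbations on the prox objective."""
        spec = spec_for(family)
        A = rng.normal(size=(3, 4))
        t = 0.7
        Z = prox_loss(spec, A, t)

        def prox_obj(W):
            return 0.5 * np.sum((A - W) ** 2) + t * eval_loss(
                spec, W, np.zeros_like(W)
            )

        base = prox_obj(Z)
        for _ in range(20):
            pert = Z + rng.normal(scale=1e-3, size=Z.shape)
            assert prox_obj(pert) >= base - 1e-10

    def test_prox_on_smooth_family_raises(self):
        with pytest.raises(UnsupportedOperationError):
            prox_loss(spec_for("euclidean"), np.zeros((2, 2)), 1.0)


class TestCenters:
    @pytest.mark.parametrize(
        "family,col,expected",
        [
            ("manhattan", [1.0, 2.0, 9.0], 2.0),
            ("euclidean", [0.0, 2.0, 4.0], 2.0),
            ("poisson_ll", [1.0, 2.0, 6.0], np.log(3.0)),
            ("poisson_dev", [1.0, 2.0, 6.0], 3.0),
            ("bernoulli_ll", [0.0, 1.0, 1.0, 1.0], np.log(3.0)),  # logit(3/4)
        ],
    )
    def test_closed_form_centers(self, family, col, expected):
        c = loss_center(spec_for(family), np.array(col)[:, None])
        assert c[0] == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("family", SMOOTH + NONSMOOTH)
    def test_center_is_columnwise_minimizer(self, family, rng):
        """Perturbing the center by +-delta never decreases the column loss."""
        spec = spec_for(family)
        X, _ = admissible_xu(family, rng, n=9)
        c = loss_center(spec, X)
        n = X.shape[0]
        base = eval_loss(spec, X, np.tile(c, (n, 1)))
        for delta in (1e-3, 1e-2, 0.1):
            for sign in (+1, -1):
                for j in range(X.shape[1]):
                    cc = c.copy()
                    cc[j] += sign * delta
                    try:
                        val = eval_loss(spec, X, np.tile(cc, (n, 1)))
                    except InvalidDomainError:
                        continue
                    assert val >= base - 1e-8 * (1 + abs(base))

    def test_degenerate_mean_clamped(self):
        # all-zero count column: log-mean center is clamped, not -inf
        c = loss_center(spec_for("poisson_ll"), np.zeros((4, 1)))
        assert np.isfinite(c[0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            loss_center(spec_for("euclidean"), np.empty((0, 0)))


class TestNullDeviance:
    def test_hand_value(self):
        # single euclidean column (0, 2): center 1, loss 0.5*(1+1)=1, pi=1
        w = null_deviance_weight(spec_for("euclidean"), np.array([[0.0], [2.0]]))
        assert w == pytest.approx(1.0)

    def test_constant_view_degenerate(self):
        with pytest.raises(DegenerateViewError):
            null_deviance_weight(spec_for("euclidean"), np.full((5, 2), 3.0))

    @pytest.mark.parametrize("family", ["euclidean", "manhattan", "bernoulli_ll",
                                        "poisson_dev", "binomial_dev"])
    def test_weight_times_null_deviance_is_one(self, family, rng):
        X, _ = admissible_xu(family, rng, n=8, p=3)
        view = make_view(X, spec_for(family))
        dev = eval_loss(view.loss, X, np.broadcast_to(view.center, X.shape))
        assert view.weight * dev == pytest.approx(1.0)


def test_spec_validation():
    with pytest.raises(ValueError):
        LossSpec("minkowski", q=0.5)
    with pytest.raises(ValueError):
        LossSpec("mahalanobis", C=np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD
    with pytest.raises(ValueError):
        LossSpec("negbin_ll", theta_nb=-1.0)
    with pytest.raises(UnsupportedOperationError):
        LossSpec("hinge")
    assert not LossSpec("minkowski", q=1.0).smooth
    assert LossSpec("minkowski", q=2.5).smooth
    assert not LossSpec("chebychev").smooth
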