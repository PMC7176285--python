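import numpy as np
import pytest

from quasiscape import VectorFieldModel


@pytest.fixture
def linear_sink():
    """Linear gradient field (-x, -y) with exact potential (x^2 + y^2)/2."""
    return VectorFieldModel(
        dimension=2,
        components=(lambda s: -s[0], lambda s: -s[1]),
        analytic_jacobian=lambda s: -np.eye(2),
        name="linear_sink",
    )


@pytest.fixture
def mixed_linear():
    """Field (-x - y, x - y): equal gradient and rotational weights."""
    A = np.array([[-1.0, -1.0], [1.0, -1.0]])
    return VectorFieldModel(
        dimension=2,
        components=(lambda s: A[0] @ s, lambda s: A[1] @ s),
        analytic_jacobian=lambda s: A,
        name="mixed_linear",
    )


@pytest.fixture
def gradient_cubic():
    """Non-separable gradient field -grad(x^2 y + y^3/3 + x^2 y^3/3).

    Symmetric Jacobian everywhere, with a quintic potential term: for
    potentials of degree <= 4 the per-cell circulation of the accumulated
    increments cancels identically and the two sweep orders coincide to
    roundoff, so a genuine O(h^2) path-dependence test needs degree 5.
    """

    def jac(s):
        x, y = s
        return np.array(
            [
                [-(2.0 * y + (2.0 / 3.0) * y**3), -(2.0 * x + 2.0 * x * y**2)],
                [-(2.0 * x + 2.0 * x * y**2), -(2.0 * y + 2.0 * x**2 * y)],
            ]
        )

    return VectorFieldModel(
        dimension=2,
        components=(
            lambda s: -(2.0 * s[0] * s[1] + (2.0 / 3.0) * s[0] * s[1] ** 3),
            lambda s: -(s[0] ** 2 + s[1] ** 2 + s[0] ** 2 * s[1] ** 2),
        ),
        analytic_jacobian=jac,
        name="gradient_cubic",
    )


def gradient_cubic_potential(x, y):
    return x**2 * y + y**3 / 3.0 + x**2 * y**3 / 3.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
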