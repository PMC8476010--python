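import numpy as np
import pytest

from rbmsim import RBM


@pytest.fixture
def decay():
    """S1 -> 0 with k = 1: dX/dt = -X, X(t) = e^-t."""
    return RBM(["S1"], A=[[1]], B=[[0]], K=[1.0], X0=[1.0])


@pytest.fixture
def fast_decay():
    """S1 -> 0 with k = 1000: the archetypal stiff linear problem."""
    return RBM(["S1"], A=[[1]], B=[[0]], K=[1000.0], X0=[1.0])


@pytest.fixture
def reversible_pair():
    """A <-> B with k1 = k2 = 1; equilibrium [0.5, 0.5] from [1, 0]."""
    return RBM(
        ["A", "B"], A=[[1, 0], [0, 1]], B=[[0, 1], [1, 0]], K=[1.0, 1.0], X0=[1.0, 0.0]
    )


@pytest.fixture
def robertson():
    """Robertson's stiff problem in mass-action form.

    A -> B (k = 0.04); B + C -> A + C (k = 1e4); 2B -> B + C (k = 3e7).
    """
    return RBM(
        ["A", "B", "C"],
        A=[[1, 0, 0], [0, 1, 1], [0, 2, 0]],
        B=[[0, 1, 0], [1, 0, 1], [0, 1, 1]],
        K=[0.04, 1e4, 3e7],
        X0=[1.0, 0.0, 0.0],
    )


@pytest.fixture
def predator_prey():
    """Mass-action Lotka-Volterra with a tunable prey self-limitation.

    X -> 2X; X + Y -> 2Y; Y -> 0; 2X -> X (damping, k = 0 row omitted).
    """

    def _make(damping: float) -> RBM:
        return RBM(
            ["prey", "pred"],
            A=[[1, 0], [1, 1], [0, 1], [2, 0]],
            B=[[2, 0], [0, 2], [0, 0], [1, 0]],
            K=[1.0, 1.0, 1.0, damping],
            X0=[1.5, 1.0],
        )

    return _make


def random_rbm(rng: np.random.Generator, n: int, m: int) -> RBM:
    """Small random RBM with integer stoichiometries in {0, 1, 2}."""
    A = rng.integers(0, 3, size=(m, n))
    B = rng.integers(0, 3, size=(m, n))
    empty = (A.sum(axis=1) + B.sum(axis=1)) == 0
    B[empty, 0] = 1
    K = rng.uniform(0.1, 2.0, m)
    X0 = rng.uniform(0.0, 2.0, n)
    return RBM([f"S{j}" for j in range(n)], A=A, B=B, K=K, X0=X0)
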