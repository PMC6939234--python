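import numpy as np
import pytest

from blanketmech import systems, synthetic


@pytest.fixture
def spec3d():
    """Minimal 3-D blanket system (eta, a, mu) with precision
    [[2,1,0],[1,3,1],[0,1,2]]: the worked example used throughout.

    Conditional modes at b = 2 are eta(b) = mu(b) = -1; the synchronization
    map has unit slope.  Not strict (Pi[a, eta] = 1), so built at blanket
    level.
    """
    part = systems.make_partition(1, 0, 1, 1)
    Pi = np.array([[2.0, 1.0, 0.0], [1.0, 3.0, 1.0], [0.0, 1.0, 2.0]])
    return systems.build_linear_system(Pi, np.zeros((3, 3)), np.eye(3), part, strict=False)


@pytest.fixture
def blanket6d():
    """Random 6-D blanket-level system with an injective b -> mu(b) map."""
    return synthetic.random_blanket_system((2, 1, 1, 2), 11, strict=False)


@pytest.fixture
def strict6d():
    """Random 6-D strict system (directed-influence zero blocks)."""
    return synthetic.random_blanket_system((2, 1, 1, 2), 11, strict=True)


@pytest.fixture
def bare1d():
    """1-D Ornstein-Uhlenbeck system: Pi = 2, Q = 0, Gamma = 1 (A = -2)."""
    part = systems.make_partition(0, 0, 0, 1, bare=True)
    return systems.build_linear_system([[2.0]], [[0.0]], [[1.0]], part, strict=False)


@pytest.fixture
def bare2d_solenoidal():
    """2-D system with a solenoidal component inside one block."""
    part = systems.make_partition(0, 0, 0, 2, bare=True)
    Pi = np.array([[2.0, 0.5], [0.5, 1.5]])
    Q = np.array([[0.0, 0.7], [-0.7, 0.0]])
    return systems.build_linear_system(Pi, Q, np.eye(2), part, strict=False)
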