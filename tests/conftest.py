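import numpy as np
import pytest

from srmf.datamodel import Direction, ResponseMatrix, SimilarityMatrix, SrmfConfig
from srmf.simulation import SimulationConfig, simulate_instance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_response():
    """4 drugs x 5 cells with two missing entries."""
    values = np.array(
        [
            [1.0, 2.0, np.nan, 4.0, 5.0],
            [0.5, np.nan, 1.5, 2.5, 3.0],
            [-1.0, -2.0, 0.0, 1.0, 2.0],
            [3.0, 1.0, 4.0, 2.0, 0.0],
        ]
    )
    return ResponseMatrix(
        [f"d{i}" for i in range(4)],
        [f"c{j}" for j in range(5)],
        values,
        direction=Direction.LOWER_IS_SENSITIVE,
    )


@pytest.fixture
def tiny_instance():
    """Small noisy low-rank problem for fit/CV tests."""
    return simulate_instance(
        SimulationConfig(m=15, n=20, k_true=3, noise_level=0.1, missing_fraction=0.1, seed=7)
    )


def random_problem(rng, m, n, K, missing=0.2):
    """Random factorization instance: (Y, W, U, V, Sd, Sc)."""
    U = rng.standard_normal((m, K))
    V = rng.standard_normal((n, K))
    Y = U @ V.T + 0.1 * rng.standard_normal((m, n))
    W = (rng.random((m, n)) >= missing).astype(float)

    def sym(k):
        A = rng.uniform(-1, 1, (k, k))
        S = (A + A.T) / 2
        np.fill_diagonal(S, 1.0)
        return S

    return Y, W, U, V, sym(m), sym(n)
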