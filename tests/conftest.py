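import numpy as np
import pytest

from wconn import Connectome


def random_connectome(
    rng: np.random.Generator,
    n: int = 8,
    p: float = 0.5,
    with_counts: bool = True,
    max_count: int = 200,
) -> Connectome:
    """Small random connectome for oracle comparisons."""
    labels = [f"v{i}" for i in range(n)]
    w = np.zeros((n, n))
    k = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w[i, j] = w[j, i] = rng.uniform(0.01, 1.0)
                k[i, j] = k[j, i] = rng.integers(1, max_count)
    return Connectome(labels, w, k if with_counts else None)


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def triangle():
    """Triangle with one weak direct edge and two strong ones."""
    w = np.array(
        [
            [0.0, 0.1, 0.6],
            [0.1, 0.0, 0.6],
            [0.6, 0.6, 0.0],
        ]
    )
    return Connectome(["n1", "n2", "n3"], w)


@pytest.fixture
def path_abc():
    """Path graph A - B - C with unit weights."""
    w = np.array(
        [
            [0.0, 1.0, 0.0],
            [1.0, 0.0, 1.0],
            [0.0, 1.0, 0.0],
        ]
    )
    return Connectome(["A", "B", "C"], w)
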