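import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from netjack import simulate_adjacency, simulate_layout


@pytest.fixture
def k3():
    return simulate_adjacency(3, "complete", weight=1.0)


@pytest.fixture
def p3():
    return simulate_adjacency(3, "path", weight=1.0)


@pytest.fixture
def block_net():
    """Well-connected 20-node two-block network."""
    return simulate_adjacency(20, "block", seed=11)


@pytest.fixture
def grid_layout():
    return simulate_layout(4, 5, 10.0, n_soz=4, seed=3)


def random_sparse_adjacency(n: int, seed: int, p_zero: float = 0.3) -> np.ndarray:
    """Random weighted adjacency with some absent edges (may disconnect)."""
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    w = rng.uniform(0.05, 1.0, size=len(iu[0]))
    w[rng.uniform(size=len(w)) < p_zero] = 0.0
    adj[iu] = w
    return adj + adj.T
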