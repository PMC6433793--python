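from __future__ import annotations

import numpy as np
import pytest

from fcnet.connectome import BinaryNetwork
from fcnet.prep import RoiTimeSeries


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def star10() -> np.ndarray:
    adj = np.zeros((10, 10), dtype=np.uint8)
    adj[0, 1:] = 1
    adj[1:, 0] = 1
    return adj


@pytest.fixture
def ring20_k4() -> np.ndarray:
    n, k = 20, 4
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            adj[i, j] = adj[j, i] = 1
    return adj


@pytest.fixture
def complete(request) -> np.ndarray:
    n = getattr(request, "param", 10)
    adj = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(adj, 0)
    return adj


def make_network(adj: np.ndarray) -> BinaryNetwork:
    n = adj.shape[0]
    s = adj.sum() / (n * (n - 1))
    return BinaryNetwork(adj, float(s))


@pytest.fixture
def sine_ts() -> RoiTimeSeries:
    """Two-column series: 0.04 Hz (mid-band) and 0.2 Hz (stop-band) at TR=2."""
    t = np.arange(512) * 2.0
    data = np.column_stack(
        [np.sin(2 * np.pi * 0.04 * t), np.sin(2 * np.pi * 0.2 * t)]
    )
    return RoiTimeSeries(data=data, tr_seconds=2.0, subject_id="sine")
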