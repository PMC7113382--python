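import numpy as np
import pytest

from waveconn import make_parcel_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


@pytest.fixture
def small_parcels():
    """10 regions: DMN 4, SN 3, FPN 3, no OTHER."""
    return make_parcel_table(10, {"DMN": 4, "SN": 3, "FPN": 3})


def random_adjacency(rng, n, p=0.3):
    """Symmetric 0/1 matrix with zero diagonal (Erdos-Renyi)."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.int8)
    return adj | adj.T


def floyd_warshall(adj):
    """Independent literal all-pairs shortest-path oracle (triple loop)."""
    n = adj.shape[0]
    dist = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def literal_efficiency(dist):
    """Eq.-1 oracle: average inverse distance over ordered pairs."""
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))
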