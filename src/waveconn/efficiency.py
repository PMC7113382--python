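"""Global, nodal and subnetwork efficiency on binary graphs.

Efficiency (Latora & Marchiori) averages inverse shortest-path lengths over
ordered node pairs:

    E = (1/n) sum_i E_i,   E_i = (1/(n-1)) sum_{j != i} 1/d_ij

with 1/inf = 0 for disconnected pairs. E is 1 on the complete graph, 0 on the
empty one. Subnetwork efficiency E_s evaluates the same quantity on the node
subset N_s of one named network, either on the induced subgraph (default —
information exchanged strictly within the subnetwork) or with whole-graph
distances restricted to member endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .graphs import BinaryAdjacency
from .parcellation import ParcelTable

__all__ = [
    "EfficiencyRecord",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_efficiency",
    "subnetwork_efficiency",
    "efficiency_record",
]

SubnetworkMode = Literal["induced", "restricted"]


def _as_matrix(adjacency) -> np.ndarray:
    if isinstance(adjacency, BinaryAdjacency):
        return adjacency.edges
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def shortest_path_lengths(adjacency) -> np.ndarray:
    """All-pairs hop counts by BFS from every node; inf for unreachable pairs."""
    a = _as_matrix(adjacency)
    return _csgraph_shortest_path(a, method="D", unweighted=True, directed=False)


def _pairwise_efficiency(dist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    return inv


def global_efficiency(adjacency) -> float:
    a = _as_matrix(adjacency)
    n = a.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    inv = _pairwise_efficiency(shortest_path_lengths(a))
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(adjacency, node: int) -> float:
    """E_i: mean inverse distance from ``node`` to every other node."""
    a = _as_matrix(adjacency)
    n = a.shape[0]
    if not 0 <= node < n:
        raise ValueError(f"node {node} not in graph of size {n}")
    if n < 2:
        raise ValueError("nodal efficiency needs at least 2 nodes")
    inv = _pairwise_efficiency(shortest_path_lengths(a))
    return float(inv[node].sum() / (n - 1))


def subnetwork_efficiency(
    adjacency, parcels: ParcelTable, network: str, mode: SubnetworkMode = "induced"
) -> float:
    """E_s over the member nodes of ``network``.

    induced: distances within the induced subgraph only (paths may not leave
    the subnetwork). restricted: whole-graph distances, member endpoints only
    (paths may route through non-member nodes). induced <= restricted always.
    """
    if mode not in ("induced", "restricted"):
        raise ValueError("mode must be 'induced' or 'restricted'")
    a = _as_matrix(adjacency)
    members = parcels.nodes_in(network)
    if members.size == 0:
        raise ValueError(f"unknown or empty network {network!r}")
    if members.size < 2:
        raise ValueError(f"network {network!r} has n_s < 2; E_s undefined")
    n_s = members.size
    if mode == "induced":
        sub = a[np.ix_(members, members)]
        inv = _pairwise_efficiency(shortest_path_lengths(sub))
    else:
        dist = shortest_path_lengths(a)[np.ix_(members, members)]
        inv = _pairwise_efficiency(dist)
    return float(inv.sum() / (n_s * (n_s - 1)))


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-subject global and per-network efficiency values."""

    subject_id: str
    e_global: float
    e_networks: dict[str, float]
    n_nodes: int
    n_s: dict[str, int]

    def __post_init__(self) -> None:
        vals = [self.e_global, *self.e_networks.values()]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("efficiency values must lie in [0, 1]")

    def to_row(self) -> dict:
        row: dict = {"subject_id": self.subject_id, "E_global": self.e_global, "n": self.n_nodes}
        for name, value in self.e_networks.items():
            row[f"E_{name}"] = value
            row[f"n_{name}"] = self.n_s[name]
        return row


def efficiency_record(
    adjacency, parcels: ParcelTable, subject_id: str, mode: SubnetworkMode = "induced"
) -> EfficiencyRecord:
    """Bundle E and every named-network E_s for one subject's graph."""
    a = _as_matrix(adjacency)
    e_networks = {
        name: subnetwork_efficiency(a, parcels, name, mode=mode) for name in parcels.network_names
    }
    return EfficiencyRecord(
        subject_id=subject_id,
        e_global=global_efficiency(a),
        e_networks=e_networks,
        n_nodes=a.shape[0],
        n_s={name: int(parcels.nodes_in(name).size) for name in parcels.network_names},
    )


def efficiency_table(records: list[EfficiencyRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])
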