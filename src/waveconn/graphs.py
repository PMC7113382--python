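"""Correlation matrices and fixed-density binarization.

Each subject's connectome is the Pearson correlation matrix of the level-of-
interest wavelet coefficient series across regions. Binarization keeps a
fixed *number of edges* (the connectivity-conservation criterion): the
retained edge count is identical for every subject, while the correlation
threshold that achieves it varies per matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "BinaryAdjacency",
    "correlation_matrix",
    "edge_count_for_density",
    "threshold_to_density",
]

ThresholdMode = Literal["signed", "absolute"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("diagonal must be 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("entries must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.region_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class BinaryAdjacency:
    """Symmetric 0/1 adjacency at a fixed edge count, zero diagonal."""

    edges: np.ndarray  # (R, R) int8
    edge_count: int
    density: float
    region_ids: np.ndarray
    threshold: float  # attained cutoff score (r or |r| of the weakest kept edge)
    mode: str = "signed"

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("edges must be square")
        if np.any(np.diag(e) != 0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(e, e.T):
            raise ValueError("edges must be symmetric")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("edges must be 0/1")
        if int(np.triu(e, 1).sum()) != self.edge_count:
            raise ValueError("edge_count inconsistent with matrix")

    @property
    def n_nodes(self) -> int:
        return self.edges.shape[0]

    def edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(np.triu(self.edges, 1))
        ids = np.asarray(self.region_ids)
        return pd.DataFrame({"i": ids[i], "j": ids[j]})


def correlation_matrix(coeff_matrix: np.ndarray, region_ids=None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of a (T, R) coefficient matrix.

    Constant columns make r undefined; the offending region is named in the
    error rather than silently propagating NaN.
    """
    x = np.asarray(coeff_matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("coeff_matrix must be 2-D (time on axis 0)")
    n_time, n_reg = x.shape
    if n_time < 3:
        raise ValueError("need at least 3 timepoints for a correlation matrix")
    if region_ids is None:
        region_ids = np.arange(n_reg)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = np.asarray(region_ids)[np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant series for region(s) {bad.tolist()}: correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, region_ids=np.asarray(region_ids))


def edge_count_for_density(n_regions: int, density: float) -> int:
    """Edges to keep at a connection density: round-half-up of d * n(n-1)/2."""
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n_pairs = n_regions * (n_regions - 1) // 2
    return int(np.floor(density * n_pairs + 0.5))


def threshold_to_density(
    corr: CorrelationMatrix, density: float, mode: ThresholdMode = "signed"
) -> BinaryAdjacency:
    """Binarize at fixed density: keep exactly the top-k off-diagonal pairs.

    ``signed`` ranks by r (strongest positive correlations win); ``absolute``
    ranks by |r|. Ties at the cutoff are broken by lexicographic (i, j) order,
    making the edge set deterministic for any input.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    n = corr.n_regions
    k = edge_count_for_density(n, density)
    if k == 0:
        raise ValueError("density implies zero edges")
    iu, ju = np.triu_indices(n, 1)
    scores = corr.values[iu, ju]
    if mode == "absolute":
        scores = np.abs(scores)
    # lexsort: last key is primary -> sort by -score, then i, then j
    order = np.lexsort((ju, iu, -scores))
    keep = order[:k]
    edges = np.zeros((n, n), dtype=np.int8)
    edges[iu[keep], ju[keep]] = 1
    edges |= edges.T
    return BinaryAdjacency(
        edges=edges,
        edge_count=k,
        density=k / (n * (n - 1) / 2.0),
        region_ids=np.asarray(corr.region_ids),
        threshold=float(scores[keep[-1]]),
        mode=mode,
    )
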