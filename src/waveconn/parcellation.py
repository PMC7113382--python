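"""Parcellation tables: region ids, coordinates and resting-state network labels.

A parcel table plays the role of a Power-style functional atlas: it fixes the
node set of every subject's graph and the node subsets (DMN, SN, FPN, ...)
over which subnetwork efficiency is evaluated. Regions not assigned to a
named network carry the label ``OTHER``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Label for regions outside every named network.
UNASSIGNED = "OTHER"


@dataclass(frozen=True)
class ParcelTable:
    """Region ids, MNI-style coordinates (mm) and network membership.

    ``region_ids`` must be unique and contiguous from 0; every region has
    exactly one network label and each named (non-``OTHER``) network must
    contain at least two regions, since efficiency over a single node is
    undefined.
    """

    region_ids: np.ndarray
    coords: np.ndarray  # (R, 3), mm
    networks: np.ndarray  # (R,) str labels

    def __post_init__(self) -> None:
        rid = np.asarray(self.region_ids)
        if rid.ndim != 1 or not np.array_equal(np.sort(rid), np.arange(rid.size)):
            raise ValueError("region_ids must be unique and contiguous from 0")
        if np.asarray(self.coords).shape != (rid.size, 3):
            raise ValueError("coords must have shape (n_regions, 3)")
        if np.asarray(self.networks).shape != (rid.size,):
            raise ValueError("one network label per region required")
        for name in self.network_names:
            if self.nodes_in(name).size < 2:
                raise ValueError(f"named network {name!r} has fewer than 2 regions")

    @property
    def n_regions(self) -> int:
        return int(np.asarray(self.region_ids).size)

    @property
    def network_names(self) -> tuple[str, ...]:
        """Named networks in first-appearance order, excluding ``OTHER``."""
        seen: list[str] = []
        for lab in self.networks:
            if lab != UNASSIGNED and lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def nodes_in(self, network: str) -> np.ndarray:
        """Indices (== region ids, in id order) of the members of ``network``."""
        order = np.argsort(self.region_ids)
        labs = np.asarray(self.networks)[order]
        return np.asarray(self.region_ids)[order][labs == network]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.asarray(self.region_ids),
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "network": np.asarray(self.networks),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParcelTable":
        return cls(
            region_ids=df["region_id"].to_numpy(),
            coords=df[["x", "y", "z"]].to_numpy(dtype=float),
            networks=df["network"].to_numpy(dtype=object),
        )

    @classmethod
    def read_tsv(cls, path) -> "ParcelTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def make_parcel_table(
    n_regions: int, network_sizes: Mapping[str, int], spacing_mm: float = 10.0
) -> ParcelTable:
    """Build a deterministic synthetic parcel table.

    The first ``network_sizes[name]`` regions are assigned to each named
    network in mapping order; the remainder are labelled ``OTHER``.
    Coordinates are laid out on a regular 3-D grid (``spacing_mm`` apart),
    centred at the origin — synthetic stand-ins, adequate for sphere-based
    ROI extraction tests and for plotting.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be positive")
    labels: list[str] = []
    for name, size in network_sizes.items():
        if size < 2:
            raise ValueError(f"network {name!r} must have at least 2 regions, got {size}")
        if len(labels) + size > n_regions:
            raise ValueError(
                f"network {name!r} (size {size}) does not fit: only "
                f"{n_regions - len(labels)} of {n_regions} regions remain"
            )
        labels.extend([name] * size)
    labels.extend([UNASSIGNED] * (n_regions - len(labels)))

    side = int(np.ceil(n_regions ** (1.0 / 3.0)))
    idx = np.arange(n_regions)
    grid = np.column_stack((idx % side, (idx // side) % side, idx // side**2))
    coords = (grid - (side - 1) / 2.0) * spacing_mm
    return ParcelTable(
        region_ids=np.arange(n_regions),
        coords=coords.astype(float),
        networks=np.asarray(labels, dtype=object),
    )
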