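"""Binary bipartite network container.

A :class:`BipartiteNetwork` holds the binary bee x plant adjacency matrix of
one observation period together with the ordered species labels of both
guilds.  The container enforces the invariants every downstream stage relies
on: entries are 0/1, species lists are duplicate-free, and no species is an
isolate (observed networks only ever contain recorded interactors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class EmptyNetworkError(ValueError):
    """Raised when a construction step would yield a network with no edge."""


@dataclass
class BipartiteNetwork:
    """Binary bee x plant interaction network.

    Parameters
    ----------
    bees, plants
        Ordered, duplicate-free species name lists; ``bees[i]`` labels row
        ``i`` of ``adjacency`` and ``plants[j]`` labels column ``j``.
    adjacency
        Binary matrix, shape ``(len(bees), len(plants))``; entry 1 records
        that the bee species was observed visiting the plant species.
    period_label
        Free-text tag of the observation window, e.g. ``"1930-1969"``.
    """

    bees: list[str]
    plants: list[str]
    adjacency: np.ndarray
    period_label: str = ""

    def __post_init__(self) -> None:
        self.bees = list(self.bees)
        self.plants = list(self.plants)
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape != (len(self.bees), len(self.plants)):
            raise ValueError(
                f"adjacency shape {a.shape} does not match "
                f"{len(self.bees)} bees x {len(self.plants)} plants"
            )
        if a.size == 0 or a.sum() == 0:
            raise EmptyNetworkError("network has no interactions")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)
        if len(set(self.bees)) != len(self.bees):
            raise ValueError("duplicate bee species names")
        if len(set(self.plants)) != len(self.plants):
            raise ValueError("duplicate plant species names")
        if (self.adjacency.sum(axis=1) == 0).any():
            raise ValueError("network contains an isolated bee species")
        if (self.adjacency.sum(axis=0) == 0).any():
            raise ValueError("network contains an isolated plant species")

    # -- dimensions -------------------------------------------------------

    @property
    def n_bees(self) -> int:
        return len(self.bees)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_interactions(self) -> int:
        """Number of distinct realized bee-plant links (sum of the matrix)."""
        return int(self.adjacency.sum())

    @property
    def n_nodes(self) -> int:
        return self.n_bees + self.n_plants

    # -- degrees and edges ------------------------------------------------

    def bee_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def plant_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def edge_set(self) -> set[tuple[str, str]]:
        """Set of ``(bee, plant)`` name pairs for every realized link."""
        rows, cols = np.nonzero(self.adjacency)
        return {(self.bees[i], self.plants[j]) for i, j in zip(rows, cols)}

    # -- construction helpers --------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        period_label: str = "",
    ) -> "BipartiteNetwork":
        """Build a network from an iterable of ``(bee, plant)`` pairs."""
        edges = list(edges)
        if not edges:
            raise EmptyNetworkError("no edges supplied")
        bees = sorted({b for b, _ in edges})
        plants = sorted({p for _, p in edges})
        bi = {b: i for i, b in enumerate(bees)}
        pi = {p: j for j, p in enumerate(plants)}
        a = np.zeros((len(bees), len(plants)), dtype=np.uint8)
        for b, p in edges:
            a[bi[b], pi[p]] = 1
        return cls(bees, plants, a, period_label)

    def subnetwork(
        self,
        bee_idx: Sequence[int] | np.ndarray,
        plant_idx: Sequence[int] | np.ndarray,
        drop_isolates: bool = True,
    ) -> "BipartiteNetwork":
        """Restrict to the given species indices.

        With ``drop_isolates`` (default) species left without any partner in
        the restriction are removed, preserving the no-isolate invariant.
        """
        bee_idx = np.asarray(bee_idx, dtype=np.int64)
        plant_idx = np.asarray(plant_idx, dtype=np.int64)
        sub = self.adjacency[np.ix_(bee_idx, plant_idx)]
        if sub.sum() == 0:
            raise EmptyNetworkError("restriction removed every interaction")
        if drop_isolates:
            keep_b = sub.sum(axis=1) > 0
            keep_p = sub.sum(axis=0) > 0
            sub = sub[np.ix_(keep_b, keep_p)]
            bee_idx = bee_idx[keep_b]
            plant_idx = plant_idx[keep_p]
        return BipartiteNetwork(
            [self.bees[i] for i in bee_idx],
            [self.plants[j] for j in plant_idx],
            sub,
            self.period_label,
        )

    def node_names(self) -> list[str]:
        """Bees followed by plants, in matrix order (node indexing used by
        the modularity machinery)."""
        return self.bees + self.plants

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"BipartiteNetwork({self.n_bees} bees x {self.n_plants} plants, "
            f"{self.n_interactions} links, period={self.period_label!r})"
        )
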