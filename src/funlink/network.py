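"""Undirected weighted interactome container.

An :class:`Interactome` is a simple undirected graph over gene ids.
Every edge carries a real ``weight`` (by convention the SVM decision
value for predicted edges, ``+1`` for experimentally curated ones) and
an ``origin`` flag, one of ``"predicted"`` or ``"experimental"``.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import networkx as nx

from .ids import GeneId, Pair, canonical_pair

ORIGINS = ("experimental", "predicted")


class Interactome:
    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction ------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[GeneId] | None = None,
    ) -> "Interactome":
        """Build from an iterable of ``(a, b)``, ``(a, b, weight)`` or
        ``(a, b, weight, origin)`` tuples.  Extra isolated ``nodes`` may
        be supplied so degree-0 genes are part of the namespace."""
        net = cls()
        if nodes is not None:
            net.add_nodes(nodes)
        for e in edges:
            net.add_edge(*e)
        return net

    def add_node(self, gene: GeneId) -> None:
        if not gene:
            raise ValueError("gene id must be non-empty")
        self._g.add_node(gene)

    def add_nodes(self, genes: Iterable[GeneId]) -> None:
        for g in genes:
            self.add_node(g)

    def add_edge(
        self,
        a: GeneId,
        b: GeneId,
        weight: float = 1.0,
        origin: str = "predicted",
    ) -> None:
        """Add (or update) an undirected edge.

        Experimental origin wins on collision: once an edge is flagged
        experimental it stays experimental regardless of later
        predicted-edge insertions.
        """
        pa, pb = canonical_pair(a, b)
        w = float(weight)
        if not math.isfinite(w):
            raise ValueError(f"edge weight must be finite, got {weight!r}")
        if origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}, got {origin!r}")
        if self._g.has_edge(pa, pb):
            old = self._g.edges[pa, pb]
            if old["origin"] == "experimental":
                return
        self._g.add_edge(pa, pb, weight=w, origin=origin)

    # -- queries -----------------------------------------------------
    @property
    def nodes(self) -> list[GeneId]:
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, gene: GeneId) -> bool:
        return self._g.has_node(gene)

    def has_edge(self, a: GeneId, b: GeneId) -> bool:
        if a == b:
            return False
        return self._g.has_edge(a, b)

    def neighbors(self, gene: GeneId) -> set[GeneId]:
        if not self._g.has_node(gene):
            raise KeyError(f"gene {gene!r} not in interactome")
        return set(self._g.neighbors(gene))

    def degree(self, gene: GeneId) -> int:
        return self._g.degree(gene) if self._g.has_node(gene) else 0

    def degree_sequence(self) -> dict[GeneId, int]:
        return {g: d for g, d in self._g.degree()}

    def edges(self) -> Iterator[tuple[Pair, float, str]]:
        """Yield ``((a, b), weight, origin)`` in canonical, sorted order."""
        for a, b in sorted(canonical_pair(a, b) for a, b in self._g.edges):
            d = self._g.edges[a, b]
            yield (a, b), d["weight"], d["origin"]

    def edge_pairs(self) -> set[Pair]:
        return {canonical_pair(a, b) for a, b in self._g.edges}

    def edge_data(self, a: GeneId, b: GeneId) -> tuple[float, str]:
        pa, pb = canonical_pair(a, b)
        d = self._g.edges[pa, pb]
        return d["weight"], d["origin"]

    def copy(self) -> "Interactome":
        out = Interactome()
        out._g = self._g.copy()
        return out

    def subset_origin(self, origin: str) -> "Interactome":
        out = Interactome()
        out.add_nodes(self._g.nodes)
        for (a, b), w, o in self.edges():
            if o == origin:
                out.add_edge(a, b, w, o)
        return out

    def to_networkx(self) -> nx.Graph:
        return self._g.copy()

    def to_index_arrays(self):
        """Return (node_list, edge index array of shape (E, 2)) for fast
        vectorized membership arithmetic."""
        import numpy as np

        nodes = self.nodes
        idx = {g: i for i, g in enumerate(nodes)}
        edges = np.array(
            [[idx[a], idx[b]] for (a, b), _, _ in self.edges()], dtype=np.int64
        ).reshape(-1, 2)
        return nodes, edges

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and {
            (p, w, o) for p, w, o in self.edges()
        } == {(p, w, o) for p, w, o in other.edges()}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
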