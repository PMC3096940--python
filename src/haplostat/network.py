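"""Minimum-spanning haplotype networks with tied alternative connections.

Builds the minimum spanning tree over the haplotype mutational-distance
matrix (plain Hamming counts over usable sites) and then appends every
non-tree edge whose weight equals the maximum edge weight on the tree
path between its endpoints, flagged ``alternative`` — the classic
minimum-spanning-network convention, in which all weight-tied connections
are displayed.

Multi-step links are kept as single weight-w edges; the edge-list writer
exposes an ``intermediate_steps`` column (w - 1) for renderers that draw
latent intermediate changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeTable
from .structure import hamming_matrix

__all__ = ["HaplotypeNetwork", "NetworkEdge", "minimum_spanning_network"]


@dataclass(frozen=True)
class NetworkEdge:
    hap_i: str
    hap_j: str
    weight: int  # mutational steps
    in_mst: bool
    alternative: bool


@dataclass
class HaplotypeNetwork:
    """Nodes (haplotypes with frequencies) plus MST and alternative edges."""

    nodes: list[str]
    frequencies: dict[str, int]
    composition: dict[str, dict[str, int]]  # hap -> population -> count
    edges: list[NetworkEdge]

    @property
    def mst_edges(self) -> list[NetworkEdge]:
        return [e for e in self.edges if e.in_mst]

    @property
    def total_mst_weight(self) -> float:
        return float(sum(e.weight for e in self.mst_edges))

    def to_graph(self, include_alternatives: bool = True) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(node, frequency=self.frequencies[node])
        for e in self.edges:
            if e.in_mst or (include_alternatives and e.alternative):
                g.add_edge(e.hap_i, e.hap_j, weight=e.weight,
                           in_mst=e.in_mst, alternative=e.alternative)
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "hap_i": e.hap_i,
                    "hap_j": e.hap_j,
                    "steps": e.weight,
                    "intermediate_steps": e.weight - 1,
                    "in_mst": e.in_mst,
                    "alternative": e.alternative,
                }
                for e in self.edges
            ]
        )

    def node_frame(self) -> pd.DataFrame:
        records = []
        for node in self.nodes:
            rec = {"hap": node, "frequency": self.frequencies[node]}
            rec.update(self.composition[node])
            records.append(rec)
        return pd.DataFrame.from_records(records).fillna(0)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_network(table: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances.

    Kruskal's algorithm with deterministic tie order (weight, then
    haplotype-id order) builds the MST; every excluded edge whose weight
    equals the maximum edge weight on the MST path between its endpoints
    is appended with ``alternative=True``.
    """
    ids = list(table.haplotype_ids)
    if not ids:
        raise ValueError("empty haplotype table")
    counts = np.asarray(table.counts)
    frequencies = {h: int(counts[i].sum()) for i, h in enumerate(ids)}
    composition = {
        h: {
            p: int(counts[i, j])
            for j, p in enumerate(table.populations)
            if counts[i, j] > 0
        }
        for i, h in enumerate(ids)
    }
    if len(ids) == 1:
        return HaplotypeNetwork([ids[0]], frequencies, composition, [])

    d = hamming_matrix(list(table.haplotype_sequences))
    all_edges = sorted(
        ((int(d[i, j]), i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))),
    )
    uf = _UnionFind(len(ids))
    tree = nx.Graph()
    tree.add_nodes_from(range(len(ids)))
    mst: list[tuple[int, int, int]] = []
    rest: list[tuple[int, int, int]] = []
    for w, i, j in all_edges:
        if uf.union(i, j):
            mst.append((w, i, j))
            tree.add_edge(i, j, weight=w)
        else:
            rest.append((w, i, j))

    edges = [NetworkEdge(ids[i], ids[j], w, True, False) for w, i, j in mst]
    for w, i, j in rest:
        path = nx.shortest_path(tree, i, j)
        path_max = max(
            tree.edges[a, b]["weight"] for a, b in zip(path[:-1], path[1:])
        )
        if w == path_max:
            edges.append(NetworkEdge(ids[i], ids[j], w, False, True))
    return HaplotypeNetwork(ids, frequencies, composition, edges)
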