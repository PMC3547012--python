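"""Minimum spanning haplotype networks with gap-as-fifth-state distances.

The network is a minimum spanning tree over pairwise step counts augmented
with every equal-cost alternative link: while growing the tree by increasing
weight, any edge whose weight equals the minimum joining two components at
that moment is retained (flagged ``alternative`` when a same-weight edge
already connected them).  Multi-step edges stand for undetected intermediate
haplotypes; an optional step limit prunes long edges.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx

from .haplotypes import HaplotypeCatalog
from .io import DataError

__all__ = [
    "HaplotypeNetwork",
    "NetworkNode",
    "NetworkEdge",
    "hap_distance",
    "build_msn",
    "size_class",
    "parsimony_limit",
    "write_gml",
    "write_edges_tsv",
]


def hap_distance(seq_a: str, seq_b: str) -> int:
    """Count differing positions; gap is a fifth symbol, N sites are skipped."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    return sum(
        1 for a, b in zip(seq_a.upper(), seq_b.upper()) if a != b and a != "N" and b != "N"
    )


def size_class(frequency: int) -> str:
    """Frequency size class: 1 small, 2-4 medium, 5-10 large, >10 largest."""
    if frequency < 1:
        raise ValueError("frequency must be >= 1")
    if frequency == 1:
        return "small"
    if frequency <= 4:
        return "medium"
    if frequency <= 10:
        return "large"
    return "largest"


@dataclass
class NetworkNode:
    label: str
    frequency: int
    locality_composition: dict[str, int] = field(default_factory=dict)

    @property
    def size_class(self) -> str:
        return size_class(self.frequency)


@dataclass(frozen=True)
class NetworkEdge:
    label_a: str
    label_b: str
    steps: int
    alternative: bool = False


@dataclass
class HaplotypeNetwork:
    species: str
    nodes: dict[str, NetworkNode]
    edges: list[NetworkEdge]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for label, node in self.nodes.items():
            g.add_node(
                label,
                frequency=node.frequency,
                size_class=node.size_class,
                localities=";".join(
                    f"{k}:{v}" for k, v in sorted(node.locality_composition.items())
                ),
            )
        for e in self.edges:
            g.add_edge(e.label_a, e.label_b, steps=e.steps, alternative=int(e.alternative))
        return g

    def components(self) -> list[set[str]]:
        comps = list(nx.connected_components(self.to_networkx()))
        return sorted((set(c) for c in comps), key=lambda c: min(c))


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_msn(catalog: HaplotypeCatalog) -> HaplotypeNetwork:
    """Minimum spanning network over one species' haplotypes.

    Kruskal growth with candidate edges sorted by (steps, label_a, label_b);
    within a weight class an edge is kept whenever it links two components
    that were distinct when the class started, so every equal-cost way of
    joining those components survives.  Node frequencies come from the
    catalogue's occurrence records (labels never observed count 1).
    """
    labels = sorted(catalog.entries)
    if not labels:
        raise DataError(f"catalog for {catalog.species!r} has no haplotypes")
    seqs = catalog.entries
    missing = [l for l in labels if seqs[l] is None]
    if missing and len(labels) > 1:
        raise DataError(
            f"cannot build network: haplotypes without sequences: {missing}"
        )

    freq = catalog.frequencies()
    loc_comp: dict[str, dict[str, int]] = {l: {} for l in labels}
    for occ in catalog.occurrences:
        comp = loc_comp[occ.haplotype_label]
        key = occ.locality or "unknown"
        comp[key] = comp.get(key, 0) + 1
    nodes = {
        l: NetworkNode(label=l, frequency=max(freq.get(l, 0), 1), locality_composition=loc_comp[l])
        for l in labels
    }
    if len(labels) == 1:
        return HaplotypeNetwork(species=catalog.species, nodes=nodes, edges=[])

    all_edges = sorted(
        (hap_distance(seqs[a], seqs[b]), a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    )
    dsu = _DSU(labels)
    edges: list[NetworkEdge] = []
    i = 0
    while i < len(all_edges):
        w = all_edges[i][0]
        j = i
        while j < len(all_edges) and all_edges[j][0] == w:
            j += 1
        # components frozen at the start of this weight class
        frozen = {l: dsu.find(l) for l in labels}
        live = _DSU(set(frozen.values()))
        for weight, a, b in all_edges[i:j]:
            fa, fb = frozen[a], frozen[b]
            if fa == fb:
                continue  # already linked by a strictly cheaper path
            merged_now = live.union(fa, fb)
            edges.append(NetworkEdge(a, b, steps=weight, alternative=not merged_now))
            dsu.union(a, b)
        i = j
    return HaplotypeNetwork(species=catalog.species, nodes=nodes, edges=edges)


def parsimony_limit(
    network: HaplotypeNetwork, max_steps: Optional[int] = None
) -> tuple[HaplotypeNetwork, list[set[str]]]:
    """Drop edges above a step limit; report the resulting components.

    ``max_steps=None`` means no limit (the statistical connection-limit
    computation of parsimony-network software is not reproduced here; the
    limit is user-supplied).
    """
    if max_steps is None:
        return network, network.components()
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0 or None")
    pruned = HaplotypeNetwork(
        species=network.species,
        nodes={l: replace(n) for l, n in network.nodes.items()},
        edges=[e for e in network.edges if e.steps <= max_steps],
    )
    return pruned, pruned.components()


def write_gml(network: HaplotypeNetwork, path) -> None:
    nx.write_gml(network.to_networkx(), str(path))


def write_edges_tsv(network: HaplotypeNetwork, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["label_a", "label_b", "steps", "alternative"])
        for e in network.edges:
            writer.writerow([e.label_a, e.label_b, e.steps, int(e.alternative)])
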