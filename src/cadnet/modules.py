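"""Girvan-Newman module extraction with a modularity-maximising cut.

Edges are removed one at a time in order of decreasing edge betweenness
(recomputed after every removal; ties broken by the lexicographically
smallest edge for determinism).  The connected components after each
removal form a dendrogram of nested partitions; modularity of every
partition is evaluated on the ORIGINAL graph and the partition with
maximum modularity (earliest on ties, i.e. the coarsest) is cut into
modules.  Module ids follow the ``networkId_index`` convention with
blocks numbered by decreasing size, then by smallest member symbol.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .prioritize import CandidateGeneSets


def edge_betweenness(graph: nx.Graph) -> dict[tuple, float]:
    """Unnormalised edge betweenness on an undirected, unweighted graph.

    Each unordered vertex pair contributes 1, split over the shortest
    paths between the pair; an edge's value is the summed share of
    shortest paths traversing it.
    """
    eb = nx.edge_betweenness_centrality(graph, normalized=False)
    return {tuple(sorted(e)): v for e, v in eb.items()}


def modularity(original_graph: nx.Graph, partition: list[set]) -> float:
    """Newman modularity Q of a partition, on the original graph.

    Q = sum_c [e_c/m - (d_c/2m)^2]; defined as 0 for an edgeless graph.
    """
    m = original_graph.number_of_edges()
    if m == 0:
        return 0.0
    return float(nx.community.modularity(original_graph, partition))


@dataclass
class Dendrogram:
    """Removal order, the nested partitions, and their modularities."""

    removal_sequence: list[tuple] = field(default_factory=list)
    partition_sequence: list[list[set]] = field(default_factory=list)
    modularity_sequence: list[float] = field(default_factory=list)


def _components(graph: nx.Graph) -> list[set]:
    return [set(c) for c in nx.connected_components(graph)]


def girvan_newman(graph: nx.Graph) -> Dendrogram:
    """Full edge-betweenness removal dendrogram down to the empty graph.

    The initial component partition is recorded first; after every
    removal of the current maximum-betweenness edge (lexicographically
    smallest among ties) the component partition and its modularity on
    the original graph are appended.  Deterministic: no randomness.
    """
    work = graph.copy()
    dendro = Dendrogram()
    dendro.partition_sequence.append(_components(work))
    dendro.modularity_sequence.append(modularity(graph, dendro.partition_sequence[0]))
    while work.number_of_edges() > 0:
        eb = edge_betweenness(work)
        top = max(eb.values())
        edge = min(e for e, v in eb.items() if v == top)
        work.remove_edge(*edge)
        dendro.removal_sequence.append(edge)
        dendro.partition_sequence.append(_components(work))
        dendro.modularity_sequence.append(
            modularity(graph, dendro.partition_sequence[-1])
        )
    return dendro


@dataclass
class Module:
    """One dense block of the selected partition."""

    module_id: str
    network_id: str
    nodes: set[str]
    contains_candidates: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.nodes)


def cut_dendrogram(dendro: Dendrogram, cut: str | int = "max_modularity") -> list[set]:
    """Select a partition: maximum modularity (earliest on ties) or a
    fixed block count ``cut=K`` (first partition with >= K blocks)."""
    if cut == "max_modularity":
        best = max(dendro.modularity_sequence)
        idx = dendro.modularity_sequence.index(best)
        return dendro.partition_sequence[idx]
    k = int(cut)
    for part in dendro.partition_sequence:
        if len(part) >= k:
            return part
    return dendro.partition_sequence[-1]


def extract_modules(
    rgpn: nx.Graph, cut: str | int = "max_modularity"
) -> list[Module]:
    """Girvan-Newman modules of an RGPN under the selected cut.

    Blocks are ordered by decreasing size then lexicographically smallest
    member, and numbered 1-based into ``networkId_index`` ids.
    """
    network_id = str(rgpn.graph.get("network_id", "net"))
    dendro = girvan_newman(rgpn)
    partition = cut_dendrogram(dendro, cut)
    blocks = sorted(partition, key=lambda b: (-len(b), min(b)))
    return [
        Module(module_id=f"{network_id}_{i}", network_id=network_id, nodes=set(b))
        for i, b in enumerate(blocks, start=1)
    ]


def select_candidate_modules(
    modules: list[Module], candidate_sets: CandidateGeneSets
) -> tuple[list[Module], list[Module]]:
    """Modules containing any candidate gene; and only those containing a
    genome-wide significant candidate (always a subset of the first)."""
    with_any: list[Module] = []
    with_significant: list[Module] = []
    for mod in modules:
        hit = mod.nodes & candidate_sets.full
        if hit:
            mod.contains_candidates = hit
            with_any.append(mod)
            if mod.nodes & candidate_sets.significant:
                with_significant.append(mod)
    return with_any, with_significant
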