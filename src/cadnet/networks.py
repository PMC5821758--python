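"""Tissue-specific regulatory gene-protein network (RGPN) construction.

Co-expression networks inferred per tissue are extended with
confidence-filtered protein-protein interactions (PPIs) in two passes:
first the PPI partners of every co-expression gene are recruited, then
PPI edges *among the recruited proteins only* are added.  Both passes
require the two interactors to be expressed (median log2 intensity at or
above a background threshold) in at least one common tissue of the
network, which keeps the extension tissue-specific.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ConfigurationError

log = logging.getLogger(__name__)

RMA_BACKGROUND = 5.0  #: log2 intensity at/above which a gene is called expressed
MIN_PPI_CONFIDENCE = 0.5

PPI_COLUMNS = ["gene_a", "gene_b", "confidence"]


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix for one tissue.

    ``scale`` is ``rma_log2`` for microarray intensities (CAD tissues)
    or ``fpkm`` for linear RNA-seq values (Tox tissues).  ``quality_tags``
    optionally flags genes with unreliable quantification ("LOWDATA",
    "FAIL"); untagged genes carry "OK".
    """

    tissue: str
    scale: str  # "rma_log2" | "fpkm"
    values: pd.DataFrame  # index: gene symbols; columns: samples
    quality_tags: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("rma_log2", "fpkm"):
            raise ConfigurationError(f"scale: unknown scale {self.scale!r}")
        if self.scale == "fpkm" and (self.values.to_numpy() < 0).any():
            raise ConfigurationError(
                f"values: negative FPKM in tissue {self.tissue!r}"
            )


@dataclass
class CoexpressionNetwork:
    """An undirected co-expression edge list with its tissue label(s)."""

    network_id: str
    tissues: tuple[str, ...]
    edges: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}


def call_expressed_genes(
    matrix: ExpressionMatrix, threshold: float = RMA_BACKGROUND
) -> set[str]:
    """Genes whose median signal across all samples is >= ``threshold``.

    Only defined for log2 microarray matrices; the boundary is inclusive,
    so a gene sitting exactly at the background level counts as expressed.
    """
    if matrix.scale != "rma_log2":
        raise ConfigurationError(
            f"scale: expressed-gene calling requires rma_log2, got {matrix.scale!r}"
        )
    if matrix.values.empty:
        return set()
    medians = matrix.values.median(axis=1)
    return set(medians.index[medians >= threshold])


def filter_ppis(
    ppis: pd.DataFrame, min_confidence: float = MIN_PPI_CONFIDENCE
) -> pd.DataFrame:
    """Keep PPIs with confidence >= ``min_confidence`` (inclusive).

    Self-pairs are dropped; duplicate unordered pairs are collapsed to a
    single row keeping the maximum confidence (interaction databases
    aggregate several sources for the same pair).
    """
    out = ppis[ppis["confidence"] >= min_confidence].copy()
    out = out[out["gene_a"] != out["gene_b"]]
    key = out.apply(
        lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1
    )
    if len(out):
        out["_key"] = key
        out = (
            out.sort_values("confidence", ascending=False)
            .drop_duplicates("_key")
            .drop(columns="_key")
        )
        out[["gene_a", "gene_b"]] = pd.DataFrame(
            [sorted((a, b)) for a, b in zip(out["gene_a"], out["gene_b"])],
            index=out.index,
        )
        out = out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return out


def _ppi_adjacency(ppis: pd.DataFrame) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in zip(ppis["gene_a"], ppis["gene_b"]):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def extend_network(
    net: CoexpressionNetwork | nx.Graph,
    ppis: pd.DataFrame,
    expressed_sets: dict[str, set[str]],
) -> nx.Graph:
    """Extend a co-expression network into an RGPN.

    Pass 1 adds, for every co-expression gene ``g``, each PPI partner
    ``p`` together with the edge ``(g, p)`` provided some tissue of the
    network has both ``g`` and ``p`` in its expressed set.  Pass 2 then
    adds PPI edges among the pass-1-recruited proteins only, under the
    same same-tissue gate; no new nodes are recruited in pass 2.

    ``ppis`` must already be confidence-filtered.  When called on an
    RGPN (a graph whose nodes carry an ``origin`` attribute), only the
    original co-expression genes seed pass 1, which makes the operation
    idempotent.
    """
    if isinstance(net, nx.Graph):
        graph = net.copy()
        tissues = tuple(graph.graph.get("tissues", ()))
        network_id = graph.graph.get("network_id", "")
    else:
        graph = nx.Graph(network_id=net.network_id, tissues=list(net.tissues))
        for a, b in net.edges:
            graph.add_node(a, origin="coexpression_gene")
            graph.add_node(b, origin="coexpression_gene")
            graph.add_edge(a, b, source="coexpression")
        tissues = net.tissues
        network_id = net.network_id
    for t in tissues:
        if t not in expressed_sets:
            raise ConfigurationError(
                f"tissues: network {network_id!r} references unknown tissue {t!r}"
            )

    def same_tissue(a: str, b: str) -> bool:
        return any(
            a in expressed_sets[t] and b in expressed_sets[t] for t in tissues
        )

    adj = _ppi_adjacency(ppis)
    seeds = [
        n for n, d in graph.nodes(data=True)
        if d.get("origin", "coexpression_gene") == "coexpression_gene"
    ]
    added: set[str] = set()
    for g in sorted(seeds):
        for p in sorted(adj.get(g, ())):
            if not same_tissue(g, p):
                continue
            if p not in graph:
                graph.add_node(p, origin="ppi_added_protein")
                added.add(p)
            if not graph.has_edge(g, p):
                graph.add_edge(g, p, source="ppi")
    # Pass 2: PPI closure restricted to the newly recruited proteins.
    for p in sorted(added):
        for q in sorted(adj.get(p, ()) & added):
            if p < q and same_tissue(p, q) and not graph.has_edge(p, q):
                graph.add_edge(p, q, source="ppi")
    log.debug(
        "network %s: %d co-expression nodes, %d proteins added",
        network_id, len(seeds), len(added),
    )
    return graph
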