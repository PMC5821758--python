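"""Rank-weighted evidence scoring of candidate genes at GWAS loci.

Each candidate gene at a locus carries six binary functional-evidence
flags (chromatin interaction, transcribed SNP, coding change, eQTL,
predicted deleterious, mouse-knockout atherosclerosis phenotype).  Each
category is assigned a rank L in 1..6 and the weight 2^(L-1), so the
weights are {1, 2, 4, 8, 16, 32}: a gene carrying only the top-ranked
category outscores any gene carrying all five lower categories.  The
gene(s) attaining the locus maximum (provided it is positive) are the
most likely causal genes; loci where no gene scores above zero remain
unassigned.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .simulate import EVIDENCE_FLAGS, TIER_SIGNIFICANT

log = logging.getLogger(__name__)

#: Default ranks: the order in which the six criteria are conventionally
#: enumerated (chromatin interaction first, mouse knockout last).
DEFAULT_RANKS = {flag: i + 1 for i, flag in enumerate(EVIDENCE_FLAGS)}


@dataclass
class PrioritizationWeights:
    """Category ranks and the derived 2^(L-1) weights."""

    rank_per_category: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RANKS)
    )

    def __post_init__(self) -> None:
        if set(self.rank_per_category) != set(EVIDENCE_FLAGS):
            raise ConfigurationError(
                "rank_per_category: must rank exactly the six evidence categories"
            )
        if sorted(self.rank_per_category.values()) != list(range(1, 7)):
            raise ConfigurationError(
                "rank_per_category: ranks must be a permutation of 1..6"
            )

    @property
    def weight_per_category(self) -> dict[str, int]:
        return {c: 2 ** (rank - 1) for c, rank in self.rank_per_category.items()}


def score_gene_evidence(
    flags: dict[str, bool], weights: PrioritizationWeights | None = None
) -> int:
    """Sum of 2^(L-1) weights over the true evidence flags; in [0, 63]."""
    weights = weights or PrioritizationWeights()
    w = weights.weight_per_category
    return sum(w[c] for c in EVIDENCE_FLAGS if flags.get(c, False))


def apply_symbol_map(
    evidence: pd.DataFrame, symbol_map: pd.DataFrame | None
) -> pd.DataFrame:
    """Map gene symbols to approved symbols; drop unmappable rows.

    ``symbol_map`` has columns ``symbol`` and ``approved``.  Rows whose
    gene has no entry are excluded (mirroring removal of candidates
    without an approved gene name) and the count is logged.
    """
    if symbol_map is None:
        return evidence
    mapping = dict(zip(symbol_map["symbol"], symbol_map["approved"]))
    mapped = evidence["gene"].map(mapping)
    dropped = int(mapped.isna().sum())
    if dropped:
        log.info("symbol mapping dropped %d evidence rows", dropped)
    out = evidence[mapped.notna()].copy()
    out["gene"] = mapped[mapped.notna()]
    return out


def prioritize_locus(
    rows: pd.DataFrame, weights: PrioritizationWeights | None = None
) -> pd.DataFrame:
    """Score one locus's candidates and mark every maximum-score gene.

    All genes attaining the locus maximum are flagged top, provided the
    maximum is positive; if every score is zero the locus is unassigned
    (no top gene).  An empty input yields an empty (unassigned) result.
    """
    weights = weights or PrioritizationWeights()
    if rows.empty:
        return pd.DataFrame(
            columns=["locus_id", "gene", "tier", "evidence_score", "is_top_at_locus"]
        )
    if rows["locus_id"].nunique() != 1:
        raise ConfigurationError("locus_id: rows passed to prioritize_locus must share one locus")
    scores = rows.apply(
        lambda r: score_gene_evidence(
            {c: bool(r[c]) for c in EVIDENCE_FLAGS}, weights
        ),
        axis=1,
    )
    out = rows[["locus_id", "gene", "tier"]].copy()
    out["evidence_score"] = scores.astype(int)
    top = out["evidence_score"].max()
    out["is_top_at_locus"] = (out["evidence_score"] == top) & (top > 0)
    return out.reset_index(drop=True)


def prioritize_all(
    evidence: pd.DataFrame,
    weights: PrioritizationWeights | None = None,
    symbol_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Prioritize every locus in an evidence table."""
    evidence = apply_symbol_map(evidence, symbol_map)
    parts = [
        prioritize_locus(sub, weights)
        for _, sub in evidence.groupby("locus_id", sort=True)
    ]
    if not parts:
        return prioritize_locus(evidence, weights)
    return pd.concat(parts, ignore_index=True)


@dataclass
class CandidateGeneSets:
    """Unique prioritized genes, overall and at genome-wide significant loci."""

    full: set[str]
    significant: set[str]

    def __post_init__(self) -> None:
        assert self.significant <= self.full


def build_candidate_sets(prioritized: pd.DataFrame) -> CandidateGeneSets:
    """Unique top genes across loci, plus the genome-wide significant subset."""
    tops = prioritized[prioritized["is_top_at_locus"]]
    full = set(tops["gene"])
    significant = set(tops.loc[tops["tier"] == TIER_SIGNIFICANT, "gene"])
    return CandidateGeneSets(full=full, significant=significant)
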