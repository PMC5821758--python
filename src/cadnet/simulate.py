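"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the structure of a multi-tissue atherosclerosis
expression study: seven CAD tissues on an RMA-like log2 scale with a
background level near 5.0, six toxicity-profiling (Tox) tissues on a
linear FPKM-like scale with zero inflation and quality tags, per-tissue
planted-partition co-expression networks, a confidence-scored PPI table,
a locus/evidence table in which one causal gene per locus carries
strictly more functional-evidence flags than its neighbours, and
annotation sets (drugs with cardiometabolic flags and ATC groups,
kinase/GPCR families, mouse phenotypes, GO terms).

Every quantity is drawn from a seeded :class:`numpy.random.Generator`
substream, so identical configurations produce byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import ATC_GROUPS, DRUG_COLUMNS, AnnotationBundle
from .errors import ConfigurationError
from .networks import (
    CoexpressionNetwork,
    ExpressionMatrix,
    call_expressed_genes,
)

CAD_TISSUES = ("AAW", "IMA", "LIV", "SM", "SF", "VF", "WB")
TOX_TISSUES = ("liver", "heart", "kidney", "cerebral cortex", "pancreas", "testis")
VASCULAR_TISSUES = ("IMA", "AAW")

EVIDENCE_FLAGS = [
    "chromatin_interaction",
    "transcribed",
    "coding_change",
    "eqtl",
    "deleterious",
    "mouse_ko_athero",
]
EVIDENCE_COLUMNS = ["locus_id", "lead_snp", "tier", "gene", *EVIDENCE_FLAGS]

TIER_SIGNIFICANT = "significant"
TIER_SUGGESTIVE = "suggestive"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-like defaults."""

    n_loci: int = 20
    genes_per_locus: int = 5
    n_tissues_cad: int = 7
    n_tissues_tox: int = 6
    n_networks: int = 6
    nodes_per_network: int = 30
    planted_modules_per_network: int = 3
    intra_module_edge_prob: float = 0.8
    inter_module_edge_prob: float = 0.02
    ppi_confidence_range: tuple[float, float] = (0.2, 1.0)
    expression_background_mean: float = 4.0
    expressed_mean: float = 7.0
    expression_sd: float = 0.5
    n_samples_per_tissue: int = 10
    expressed_fraction: float = 0.7
    noise_flag_prob: float = 0.1
    significant_tier_prob: float = 0.5
    tox_zero_prob: float = 0.05
    tox_lowdata_prob: float = 0.02
    tox_fail_prob: float = 0.01
    n_extra_proteins: int = 40
    n_decoy_ppis: int = 60
    annotation_set_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "drug_targets": 40,
            "kinases": 20,
            "gpcrs": 15,
            "mouse": 25,
            "go_terms": 15,
            "go_term_size": 12,
        }
    )
    cardiometabolic_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_loci": self.n_loci,
            "genes_per_locus": self.genes_per_locus,
            "n_tissues_cad": self.n_tissues_cad,
            "n_tissues_tox": self.n_tissues_tox,
            "n_networks": self.n_networks,
            "nodes_per_network": self.nodes_per_network,
            "planted_modules_per_network": self.planted_modules_per_network,
            "n_samples_per_tissue": self.n_samples_per_tissue,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name}: must be a count >= 1, got {value}")
        probs = {
            "intra_module_edge_prob": self.intra_module_edge_prob,
            "inter_module_edge_prob": self.inter_module_edge_prob,
            "expressed_fraction": self.expressed_fraction,
            "noise_flag_prob": self.noise_flag_prob,
            "significant_tier_prob": self.significant_tier_prob,
            "tox_zero_prob": self.tox_zero_prob,
            "tox_lowdata_prob": self.tox_lowdata_prob,
            "tox_fail_prob": self.tox_fail_prob,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}: must lie in [0,1], got {value}")
        if self.intra_module_edge_prob <= self.inter_module_edge_prob:
            raise ConfigurationError(
                "intra_module_edge_prob: must exceed inter_module_edge_prob"
            )
        lo, hi = self.ppi_confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"ppi_confidence_range: must be an interval within [0,1], got {(lo, hi)}"
            )
        if not self.n_tissues_cad <= len(CAD_TISSUES):
            raise ConfigurationError(
                f"n_tissues_cad: at most {len(CAD_TISSUES)} supported"
            )
        if not self.n_tissues_tox <= len(TOX_TISSUES):
            raise ConfigurationError(
                f"n_tissues_tox: at most {len(TOX_TISSUES)} supported"
            )

    # -- derived -----------------------------------------------------
    @property
    def cad_tissues(self) -> tuple[str, ...]:
        return CAD_TISSUES[: self.n_tissues_cad]

    @property
    def tox_tissues(self) -> tuple[str, ...]:
        return TOX_TISSUES[: self.n_tissues_tox]

    def gene_universe(self) -> list[str]:
        n = self.n_networks * self.nodes_per_network + self.n_extra_proteins
        return [f"G{i:04d}" for i in range(1, n + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class GroundTruth:
    """Planted structure the generators commit to."""

    causal_gene_per_locus: dict[str, str] = field(default_factory=dict)
    planted_module_membership: dict[str, tuple[str, int]] = field(
        default_factory=dict
    )
    planted_expressed_sets: dict[tuple[str, str], bool] = field(
        default_factory=dict
    )


# ---------------------------------------------------------------------------
# Locus evidence
# ---------------------------------------------------------------------------

def generate_locus_evidence(
    config: SimulationConfig, ground_truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-locus candidate genes with six binary evidence flags.

    Each locus designates one causal gene that receives strictly more
    flags than any co-locus gene; non-causal genes draw each flag from a
    sparse Bernoulli model (capped at five flags so the causal gene can
    always dominate).  Loci are tiered genome-wide significant or
    suggestive.
    """
    config.validate()
    gt = ground_truth or GroundTruth()
    rng = config.rng(1)
    universe = config.gene_universe()
    if config.n_loci * config.genes_per_locus > len(universe):
        raise ConfigurationError(
            "n_loci: n_loci * genes_per_locus exceeds the gene universe"
        )
    picked = rng.choice(
        len(universe), size=config.n_loci * config.genes_per_locus, replace=False
    )
    rows = []
    for i in range(config.n_loci):
        locus = f"L{i + 1:03d}"
        snp = f"rs{100000 + i}"
        tier = (
            TIER_SIGNIFICANT
            if rng.random() < config.significant_tier_prob
            else TIER_SUGGESTIVE
        )
        genes = [
            universe[j]
            for j in picked[
                i * config.genes_per_locus : (i + 1) * config.genes_per_locus
            ]
        ]
        causal_idx = int(rng.integers(len(genes)))
        flag_counts = []
        flag_rows = []
        for k, gene in enumerate(genes):
            if k == causal_idx:
                flag_rows.append(None)  # filled after the noise draws
                flag_counts.append(-1)
                continue
            flags = rng.random(6) < config.noise_flag_prob
            if flags.sum() > 5:  # keep headroom for the causal gene
                on = np.flatnonzero(flags)
                flags[on[int(rng.integers(len(on)))]] = False
            flag_rows.append(flags)
            flag_counts.append(int(flags.sum()))
        max_other = max(c for c in flag_counts if c >= 0) if len(genes) > 1 else 0
        n_causal = int(rng.integers(max_other + 1, 7))
        # The causal gene's evidence sits in the strongest (highest-rank)
        # categories: with k+1 top-weighted flags it outscores any k-flag
        # gene under every 2^(L-1) weighting, so the planted gene is
        # dominant in both flag count and weighted score.
        causal_flags = np.zeros(6, dtype=bool)
        causal_flags[6 - n_causal :] = True
        flag_rows[causal_idx] = causal_flags
        gt.causal_gene_per_locus[locus] = genes[causal_idx]
        for gene, flags in zip(genes, flag_rows):
            rows.append(
                dict(
                    locus_id=locus,
                    lead_snp=snp,
                    tier=tier,
                    gene=gene,
                    **{f: int(v) for f, v in zip(EVIDENCE_FLAGS, flags)},
                )
            )
    return pd.DataFrame(rows, columns=EVIDENCE_COLUMNS), gt


# ---------------------------------------------------------------------------
# Expression panels
# ---------------------------------------------------------------------------

def generate_expression_panel(
    config: SimulationConfig, ground_truth: GroundTruth | None = None
) -> tuple[
    dict[str, ExpressionMatrix],
    dict[str, ExpressionMatrix],
    pd.DataFrame,
    GroundTruth,
]:
    """CAD (log2) and Tox (FPKM) panels plus vascular presence fractions.

    Expression follows a two-component model per (gene, tissue): a
    background normal around 4.0 and an expressed normal around 7.0
    (sd 0.5 each), so the background threshold 5.0 separates the classes
    with a known confusion rate.  The liver level is drawn once and
    feeds both panels (log2 samples for CAD, linearised FPKM for Tox).
    Tox matrices carry zero inflation and LOWDATA/FAIL quality tags.
    """
    config.validate()
    gt = ground_truth or GroundTruth()
    rng = config.rng(2)
    genes = config.gene_universe()
    n_genes = len(genes)
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples_per_tissue)]

    # Shared per-gene liver level, referenced by both panels.
    liver_expressed = rng.random(n_genes) < config.expressed_fraction
    liver_mu = np.where(
        liver_expressed, config.expressed_mean, config.expression_background_mean
    )

    cad_panel: dict[str, ExpressionMatrix] = {}
    for tissue in config.cad_tissues:
        if tissue == "LIV":
            expressed = liver_expressed
            mu = liver_mu
        else:
            expressed = rng.random(n_genes) < config.expressed_fraction
            mu = np.where(
                expressed, config.expressed_mean, config.expression_background_mean
            )
        values = rng.normal(
            mu[:, None], config.expression_sd, size=(n_genes, len(samples))
        )
        cad_panel[tissue] = ExpressionMatrix(
            tissue=tissue,
            scale="rma_log2",
            values=pd.DataFrame(np.clip(values, 0.0, None), index=genes, columns=samples),
        )
        for g, e in zip(genes, expressed):
            gt.planted_expressed_sets[(g, tissue)] = bool(e)

    tox_panel: dict[str, ExpressionMatrix] = {}
    for tissue in config.tox_tissues:
        if tissue == "liver":
            mu = liver_mu
        else:
            expressed = rng.random(n_genes) < config.expressed_fraction
            mu = np.where(
                expressed, config.expressed_mean, config.expression_background_mean
            )
        log2_vals = rng.normal(
            mu[:, None], config.expression_sd, size=(n_genes, len(samples))
        )
        values = np.exp2(log2_vals)
        zeros = rng.random(values.shape) < config.tox_zero_prob
        values[zeros] = 0.0
        tag_draw = rng.random(n_genes)
        tags = np.where(
            tag_draw < config.tox_fail_prob,
            "FAIL",
            np.where(tag_draw < config.tox_fail_prob + config.tox_lowdata_prob,
                     "LOWDATA", "OK"),
        )
        tox_panel[tissue] = ExpressionMatrix(
            tissue=tissue,
            scale="fpkm",
            values=pd.DataFrame(values, index=genes, columns=samples),
            quality_tags=pd.Series(tags, index=genes),
        )

    vascular = {}
    for tissue in VASCULAR_TISSUES:
        frac = np.empty(n_genes)
        for i, g in enumerate(genes):
            if gt.planted_expressed_sets.get((g, tissue), False):
                frac[i] = rng.uniform(0.5, 1.0)
            else:
                frac[i] = rng.uniform(0.0, 0.5)
        vascular[tissue] = frac
    vascular_df = pd.DataFrame(vascular, index=pd.Index(genes, name="gene"))
    return cad_panel, tox_panel, vascular_df, gt


# ---------------------------------------------------------------------------
# Networks and PPIs
# ---------------------------------------------------------------------------

def generate_networks_and_ppis(
    config: SimulationConfig,
    cad_panel: dict[str, ExpressionMatrix],
    ground_truth: GroundTruth | None = None,
) -> tuple[list[CoexpressionNetwork], pd.DataFrame, GroundTruth]:
    """Planted-partition co-expression networks and a scored PPI table.

    Every network is assigned one or two CAD tissues and populated with
    genes called expressed there (so downstream tissue gating is
    satisfiable), then partitioned into planted modules wired with
    ``intra_module_edge_prob`` inside and ``inter_module_edge_prob``
    between blocks.  The PPI table mixes within-module pairs,
    between-module pairs, extension pairs recruiting extra proteins,
    pairs among those proteins, and random decoys; confidences span the
    configured range, so some rows fall below the 0.5 filter.
    """
    config.validate()
    gt = ground_truth or GroundTruth()
    rng = config.rng(3)
    genes = config.gene_universe()
    expressed_sets = {
        t: call_expressed_genes(m) for t, m in cad_panel.items()
    }
    non_liver = [t for t in config.cad_tissues if t != "LIV"] or list(
        config.cad_tissues
    )

    available = set(genes)
    networks: list[CoexpressionNetwork] = []
    lo, hi = config.ppi_confidence_range
    ppi_rows: list[tuple[str, str, float]] = []

    def draw_conf() -> float:
        return float(rng.uniform(lo, hi))

    for k in range(config.n_networks):
        network_id = str(k + 1)
        if k % 3 == 2 and len(non_liver) >= 2:  # every third network spans 2 tissues
            idx = rng.choice(len(non_liver), size=2, replace=False)
            tissues = tuple(non_liver[i] for i in idx)
        else:
            tissues = (non_liver[k % len(non_liver)],)
        eligible = sorted(
            available & set().union(*(expressed_sets[t] for t in tissues))
        )
        if len(eligible) < config.nodes_per_network:
            raise ConfigurationError(
                "nodes_per_network: not enough expressed genes left for "
                f"network {network_id} (have {len(eligible)})"
            )
        chosen = [
            eligible[i]
            for i in rng.choice(
                len(eligible), size=config.nodes_per_network, replace=False
            )
        ]
        available -= set(chosen)
        # Near-equal planted blocks.
        n_blocks = config.planted_modules_per_network
        sizes = np.full(n_blocks, len(chosen) // n_blocks)
        sizes[: len(chosen) % n_blocks] += 1
        membership: dict[str, int] = {}
        pos = 0
        for b, size in enumerate(sizes, start=1):
            for node in chosen[pos : pos + size]:
                membership[node] = b
                gt.planted_module_membership[node] = (network_id, b)
            pos += size
        edges = []
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                a, b = chosen[i], chosen[j]
                p = (
                    config.intra_module_edge_prob
                    if membership[a] == membership[b]
                    else config.inter_module_edge_prob
                )
                if rng.random() < p:
                    edges.append((a, b))
        networks.append(CoexpressionNetwork(network_id, tissues, edges))

        # PPIs anchored in this network.
        n_within = max(2, config.nodes_per_network // 10)
        for _ in range(n_within):
            b = int(rng.integers(1, n_blocks + 1))
            block = [n for n, m in membership.items() if m == b]
            if len(block) >= 2:
                i, j = rng.choice(len(block), size=2, replace=False)
                ppi_rows.append((block[i], block[j], draw_conf()))
        for _ in range(max(1, n_within // 2)):
            i, j = rng.choice(len(chosen), size=2, replace=False)
            ppi_rows.append((chosen[i], chosen[j], draw_conf()))
        # Extension pairs: recruit extra proteins expressed in a network tissue.
        extras = sorted(
            (set(genes) - set(chosen))
            & set().union(*(expressed_sets[t] for t in tissues))
        )
        recruited = []
        n_ext = max(2, config.nodes_per_network // 6)
        for _ in range(n_ext):
            if not extras:
                break
            g = chosen[int(rng.integers(len(chosen)))]
            p = extras[int(rng.integers(len(extras)))]
            ppi_rows.append((g, p, float(rng.uniform(max(lo, 0.5), hi))))
            recruited.append(p)
        for _ in range(max(1, n_ext // 3)):
            if len(recruited) >= 2:
                i, j = rng.choice(len(recruited), size=2, replace=False)
                if recruited[i] != recruited[j]:
                    ppi_rows.append(
                        (recruited[i], recruited[j],
                         float(rng.uniform(max(lo, 0.5), hi)))
                    )

    for _ in range(config.n_decoy_ppis):
        i, j = rng.choice(len(genes), size=2, replace=False)
        ppi_rows.append((genes[i], genes[j], draw_conf()))

    ppis = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "confidence"])
    ppis["confidence"] = ppis["confidence"].round(4)
    return networks, ppis, gt


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

def generate_annotation_sets(
    config: SimulationConfig,
    genes: list[str] | None = None,
    vascular_presence: pd.DataFrame | None = None,
    cardiometabolic_bias_genes: set[str] | None = None,
) -> AnnotationBundle:
    """Drug, family, mouse and GO annotation sets over the gene universe.

    ``cardiometabolic_bias_genes`` optionally plants extra cardiometabolic
    drug rows on the given genes (used to build positive controls for the
    score-validation statistics).
    """
    config.validate()
    genes = genes if genes is not None else config.gene_universe()
    sizes = config.annotation_set_sizes
    rng = config.rng(4)
    for name in ("drug_targets", "kinases", "gpcrs", "mouse"):
        if sizes.get(name, 0) > len(genes):
            raise ConfigurationError(
                f"annotation_set_sizes[{name!r}]: exceeds universe size {len(genes)}"
            )

    def sample(n: int) -> list[str]:
        return [genes[i] for i in rng.choice(len(genes), size=n, replace=False)]

    atc_codes = sorted(ATC_GROUPS)
    drug_rows = []
    drug_counter = 0
    for gene in sample(sizes["drug_targets"]):
        for _ in range(int(rng.integers(1, 4))):
            drug_counter += 1
            cardio = bool(rng.random() < config.cardiometabolic_rate)
            code = "C" if cardio and rng.random() < 0.7 else atc_codes[
                int(rng.integers(len(atc_codes)))
            ]
            drug_rows.append((gene, f"DRUG{drug_counter:04d}", cardio, code))
    if cardiometabolic_bias_genes:
        for gene in sorted(cardiometabolic_bias_genes):
            drug_counter += 1
            drug_rows.append((gene, f"DRUG{drug_counter:04d}", True, "C"))
    drug_table = pd.DataFrame(drug_rows, columns=DRUG_COLUMNS)

    kinases = set(sample(sizes["kinases"]))
    gpcrs = set(sample(sizes["gpcrs"]))  # may overlap kinases; union dedups
    mouse = set(sample(sizes["mouse"]))
    go = {
        f"GO:{7000000 + i:07d}": set(sample(sizes["go_term_size"]))
        for i in range(sizes["go_terms"])
    }
    return AnnotationBundle(
        drug_table=drug_table,
        family_set=kinases | gpcrs,
        mouse_set=mouse,
        go=go,
        vascular_presence=vascular_presence,
    )


def generate_module_score_benchmark(
    n_modules: int = 100,
    size_range: tuple[int, int] = (15, 40),
    drug_target_rate: float = 0.3,
    cardiometabolic_rate: float = 0.3,
    enrichment_effect: float = 0.35,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, set[str]], AnnotationBundle]:
    """A scored module set for calibrating the validation statistics.

    Emulates the post-scoring state of the pipeline: ``n_modules``
    modules with disjoint member genes, Gaussian CAD-feasibility scores,
    and a drug table in which each gene is drug-targeted with
    ``drug_target_rate`` and each targeted gene cardiometabolic with
    ``cardiometabolic_rate``.  With ``enrichment_effect > 0``, extra
    cardiometabolic target rows are planted with probability rising
    linearly with the module's score rank (reaching ``enrichment_effect``
    at the top), producing the positive-control association between
    module score and cardiometabolic targeting; with 0 the annotations
    are independent of the scores (the null).
    """
    rng = np.random.default_rng(seed)
    members: dict[str, set[str]] = {}
    scores = []
    drug_rows = []
    drug_counter = 0
    for i in range(n_modules):
        mid = f"mod{i:03d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        genes = [f"{mid}_G{j:02d}" for j in range(size)]
        members[mid] = set(genes)
        scores.append((mid, float(rng.normal(0.0, 1.0))))
        for g in genes:
            if rng.random() < drug_target_rate:
                drug_counter += 1
                cardio = bool(rng.random() < cardiometabolic_rate)
                drug_rows.append((g, f"DRUG{drug_counter:05d}", cardio, "C"))
    module_scores = pd.DataFrame(scores, columns=["module_id", "score"])
    if enrichment_effect > 0:
        ranked = module_scores.sort_values("score")["module_id"].tolist()
        for rank, mid in enumerate(ranked):
            p_extra = enrichment_effect * rank / max(n_modules - 1, 1)
            for g in sorted(members[mid]):
                if rng.random() < p_extra:
                    drug_counter += 1
                    drug_rows.append((g, f"DRUG{drug_counter:05d}", True, "C"))
    bundle = AnnotationBundle(pd.DataFrame(drug_rows, columns=DRUG_COLUMNS))
    return module_scores, members, bundle


def simulate_all(
    config: SimulationConfig,
) -> dict:
    """Run all four generators in dependency order; return a dict of inputs."""
    gt = GroundTruth()
    evidence, gt = generate_locus_evidence(config, gt)
    cad_panel, tox_panel, vascular, gt = generate_expression_panel(config, gt)
    networks, ppis, gt = generate_networks_and_ppis(config, cad_panel, gt)
    bundle = generate_annotation_sets(
        config, config.gene_universe(), vascular_presence=vascular
    )
    return dict(
        evidence=evidence,
        cad_panel=cad_panel,
        tox_panel=tox_panel,
        vascular=vascular,
        networks=networks,
        ppis=ppis,
        annotations=bundle,
        ground_truth=gt,
    )
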