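"""End-to-end orchestration: simulate -> prioritize -> build networks ->
detect modules -> score -> enrich -> validate.

Each stage reads and writes well-known files inside one artifact
directory, so any stage can be re-run (or resumed) from the cached
outputs of the previous ones.  A YAML manifest records the full
configuration and seed; re-running with the same configuration
reproduces every artifact byte for byte.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .annotations import AnnotationBundle
from .enrichment import (
    atc_enrichment,
    drug_enrichment,
    go_enrichment,
    main_go_term,
)
from .errors import ConfigurationError
from .modules import extract_modules, select_candidate_modules
from .networks import (
    MIN_PPI_CONFIDENCE,
    RMA_BACKGROUND,
    call_expressed_genes,
    extend_network,
    filter_ppis,
)
from .prioritize import (
    CandidateGeneSets,
    PrioritizationWeights,
    build_candidate_sets,
    prioritize_all,
)
from .scoring import cad_tox_expression_score, module_feasibility, score_genes
from .simulate import TIER_SIGNIFICANT, SimulationConfig, simulate_all
from .validation import (
    DEFAULT_RATIO_CAP,
    fill_group_statistics,
    quintile_split,
    validation_report,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters (defaults follow the published analysis) plus the
    simulation block that generates the inputs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    expr_threshold: float = RMA_BACKGROUND
    min_confidence: float = MIN_PPI_CONFIDENCE
    cut: str | int = "max_modularity"
    top_n: int = 25
    ratio_cap: float = DEFAULT_RATIO_CAP
    alpha: float = 0.05
    ks_method: str = "asymp"
    category_ranks: dict[str, int] | None = None

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["ppi_confidence_range"] = list(
            self.simulation.ppi_confidence_range
        )
        return d


# ---------------------------------------------------------------------------
# Stages (each reads/writes the artifact directory)
# ---------------------------------------------------------------------------

def stage_simulate(out: Path, config: PipelineConfig) -> dict:
    sim = simulate_all(config.simulation)
    inputs = out / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    sim["evidence"].to_csv(inputs / "evidence.tsv", sep="\t", index=False)
    io.write_expression_panel(sim["cad_panel"], inputs / "expression", "cad")
    io.write_expression_panel(sim["tox_panel"], inputs / "expression", "tox")
    io.write_networks(sim["networks"], inputs / "networks.tsv")
    sim["ppis"].to_csv(inputs / "ppis.tsv", sep="\t", index=False)
    sim["annotations"].write(inputs / "annotations")
    genes = config.simulation.gene_universe()
    pd.DataFrame({"symbol": genes, "approved": genes}).to_csv(
        inputs / "symbol_map.tsv", sep="\t", index=False
    )
    return sim


def stage_prioritize(out: Path, config: PipelineConfig) -> pd.DataFrame:
    inputs = out / "inputs"
    evidence = pd.read_csv(inputs / "evidence.tsv", sep="\t")
    symbol_map = pd.read_csv(inputs / "symbol_map.tsv", sep="\t")
    weights = (
        PrioritizationWeights(dict(config.category_ranks))
        if config.category_ranks
        else PrioritizationWeights()
    )
    prioritized = prioritize_all(evidence, weights, symbol_map)
    prioritized.to_csv(out / "prioritized_genes.tsv", sep="\t", index=False)
    n_unassigned = (
        prioritized.groupby("locus_id")["is_top_at_locus"].any().eq(False).sum()
    )
    log.info(
        "prioritized %d loci (%d unassigned)",
        prioritized["locus_id"].nunique(), n_unassigned,
    )
    return prioritized


def _load_candidates(out: Path) -> CandidateGeneSets:
    prioritized = pd.read_csv(out / "prioritized_genes.tsv", sep="\t")
    return build_candidate_sets(prioritized)


def stage_build_networks(out: Path, config: PipelineConfig) -> list:
    inputs = out / "inputs"
    cad_panel = io.read_expression_panel(inputs / "expression", "cad", "rma_log2")
    expressed_sets = {
        t: call_expressed_genes(m, config.expr_threshold)
        for t, m in cad_panel.items()
    }
    ppis = filter_ppis(
        pd.read_csv(inputs / "ppis.tsv", sep="\t"), config.min_confidence
    )
    networks = io.read_networks(inputs / "networks.tsv")
    rgpn_dir = out / "rgpn"
    rgpn_dir.mkdir(parents=True, exist_ok=True)
    rgpns = []
    for net in networks:
        rgpn = extend_network(net, ppis, expressed_sets)
        io.write_rgpn(rgpn, rgpn_dir / f"{net.network_id}.graphml")
        rgpns.append(rgpn)
    log.info("built %d RGPNs (%d PPIs after filtering)", len(rgpns), len(ppis))
    return rgpns


def _load_rgpns(out: Path) -> list:
    return [io.read_rgpn(p) for p in sorted((out / "rgpn").glob("*.graphml"))]


def stage_detect_modules(out: Path, config: PipelineConfig) -> list:
    rgpns = _load_rgpns(out)
    candidates = _load_candidates(out)
    modules = []
    for rgpn in rgpns:
        modules.extend(extract_modules(rgpn, config.cut))
    with_any, with_significant = select_candidate_modules(modules, candidates)
    io.write_modules(modules, out / "modules.tsv")
    io.write_modules(with_significant, out / "modules_selected.tsv")
    log.info(
        "%d modules, %d with any candidate, %d with a significant candidate",
        len(modules), len(with_any), len(with_significant),
    )
    return modules


def stage_score(out: Path, config: PipelineConfig) -> pd.DataFrame:
    inputs = out / "inputs"
    cad_panel = io.read_expression_panel(inputs / "expression", "cad", "rma_log2")
    tox_panel = io.read_expression_panel(inputs / "expression", "tox", "fpkm")
    bundle = AnnotationBundle.read(inputs / "annotations")
    candidates = _load_candidates(out)
    expr_scores = cad_tox_expression_score(cad_panel, tox_panel)
    rgpns = _load_rgpns(out)
    selected = io.read_modules(out / "modules_selected.tsv")
    gene_score_parts = []
    by_network = {g.graph["network_id"]: g for g in rgpns}
    for nid, rgpn in sorted(by_network.items()):
        scores = score_genes(rgpn, candidates.full, expr_scores, bundle)
        scores.insert(0, "network_id", nid)
        gene_score_parts.append(scores)
    gene_scores = pd.concat(gene_score_parts, ignore_index=True)
    gene_scores.to_csv(out / "gene_scores.tsv", sep="\t", index=False)
    rows = []
    for mod in selected:
        net_scores = gene_scores[gene_scores["network_id"] == mod.network_id]
        mf = module_feasibility(mod, net_scores)
        rows.append(
            dict(module_id=mf.module_id, network_id=mod.network_id,
                 size=mf.size, score=mf.score)
        )
    module_scores = pd.DataFrame(
        rows, columns=["module_id", "network_id", "size", "score"]
    ).sort_values(["score", "module_id"], ascending=[False, True])
    module_scores.to_csv(out / "module_scores.tsv", sep="\t", index=False)
    return module_scores


def stage_enrich(out: Path, config: PipelineConfig) -> pd.DataFrame:
    inputs = out / "inputs"
    bundle = AnnotationBundle.read(inputs / "annotations")
    rgpns = _load_rgpns(out)
    universe = set().union(*(set(g.nodes) for g in rgpns)) if rgpns else set()
    selected = io.read_modules(out / "modules_selected.tsv")
    module_scores = pd.read_csv(
        out / "module_scores.tsv", sep="\t", dtype={"module_id": str}
    ).set_index("module_id")
    enrich_dir = out / "enrichment"
    enrich_dir.mkdir(parents=True, exist_ok=True)
    go_rows, atc_frames, summary_rows = [], [], []
    for mod in selected:
        go_res = go_enrichment(mod.nodes, bundle.go, universe)
        for r in go_res:
            go_rows.append(
                dict(module_id=mod.module_id, term=r.unit, overlap=r.table[0],
                     odds_ratio=r.odds_ratio, p_value=r.p_value, q_value=r.q_value)
            )
        main = main_go_term(go_res)
        overall, cardio = drug_enrichment(mod.nodes, bundle, universe)
        atc = atc_enrichment(mod.nodes, bundle, universe, config.alpha)
        atc.insert(0, "module_id", mod.module_id)
        atc_frames.append(atc)
        summary_rows.append(
            dict(
                module_id=mod.module_id,
                size=mod.size,
                score=float(module_scores["score"].get(mod.module_id, float("nan"))),
                candidate_genes=";".join(sorted(mod.contains_candidates)),
                main_go_term=main.unit if main else "",
                main_go_q=main.q_value if main else float("nan"),
                drug_target_nodes=overall.table[0],
                drug_target_p=overall.p_value,
                cardiometabolic_nodes=cardio.table[0],
                cardiometabolic_p=cardio.p_value,
            )
        )
    pd.DataFrame(go_rows).to_csv(enrich_dir / "go.tsv", sep="\t", index=False)
    if atc_frames:
        pd.concat(atc_frames, ignore_index=True).to_csv(
            enrich_dir / "atc.tsv", sep="\t", index=False
        )
    summary = pd.DataFrame(summary_rows)
    if len(summary):
        summary = summary.sort_values(
            ["score", "module_id"], ascending=[False, True]
        )
    summary.to_csv(enrich_dir / "summary.tsv", sep="\t", index=False)
    return summary


def stage_validate(out: Path, config: PipelineConfig) -> pd.DataFrame:
    inputs = out / "inputs"
    bundle = AnnotationBundle.read(inputs / "annotations")
    module_scores = pd.read_csv(
        out / "module_scores.tsv", sep="\t", dtype={"module_id": str}
    )
    selected = io.read_modules(out / "modules_selected.tsv")
    members = {m.module_id: m.nodes for m in selected}
    groups = quintile_split(module_scores, top_n=config.top_n)
    fill_group_statistics(groups, members, bundle, config.ratio_cap)
    summary, pairwise = validation_report(groups, config.ks_method)
    summary.to_csv(out / "validation_report.tsv", sep="\t", index=False)
    pairwise.to_csv(out / "validation_pairwise.tsv", sep="\t", index=False)
    return summary


STAGES = [
    ("simulate", stage_simulate),
    ("prioritize", stage_prioritize),
    ("build-networks", stage_build_networks),
    ("detect-modules", stage_detect_modules),
    ("score", stage_score),
    ("enrich", stage_enrich),
    ("validate", stage_validate),
]


def run_all(config: PipelineConfig, out: Path, from_stage: str | None = None) -> Path:
    """Run the full pipeline into ``out``; optionally resume at a stage.

    Fails fast with the offending stage named; writes a manifest of the
    full configuration so any run can be reproduced exactly.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    names = [n for n, _ in STAGES]
    if from_stage and from_stage not in names:
        raise ConfigurationError(f"from_stage: unknown stage {from_stage!r}")
    start = names.index(from_stage) if from_stage else 0
    for name, fn in STAGES[start:]:
        log.info("stage %s", name)
        try:
            fn(out, config)
        except Exception as exc:  # annotate the failing stage
            raise type(exc)(f"stage {name}: {exc}") from exc
    import cadnet

    io.write_manifest(
        out / "manifest.yaml",
        dict(config=config.to_dict(), seed=config.seed, version=cadnet.__version__),
    )
    return out
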