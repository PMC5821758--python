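"""Six-component gene feasibility scores and module CAD-feasibility scores.

Each gene/protein node of an RGPN is scored on six categories:

1. distance to the nearest CAD candidate gene on the full RGPN
   (0 hops -> 4, 1 -> 2, 2 -> 1, further/unreachable -> 0);
2. expression in CAD tissues relative to toxicity-profiling tissues,
   liver-normalised and scaled to [-2, 2];
3. vascular expression (present call in >=50% of samples of either
   arterial tissue -> 1);
4. druggable gene family (kinase or GPCR -> 2);
5. existing drug (>=1 drug-gene interaction -> 2);
6. mouse atherosclerosis phenotype (-> 1).

The integrated gene score is the plain sum (range [-2, 12]); a module's
CAD-feasibility score is the mean integrated score over its members,
hence bounded by the same interval.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .annotations import AnnotationBundle
from .errors import ConfigurationError, LookupError_
from .modules import Module
from .networks import ExpressionMatrix

DISTANCE_SCORES = {0: 4, 1: 2, 2: 1}
VASCULAR_PRESENCE_THRESHOLD = 0.5
FPKM_ZERO_REPLACEMENT = 0.5

COMPONENT_COLUMNS = [
    "distance_component",
    "expression_component",
    "vascular_component",
    "family_component",
    "drug_component",
    "mouse_component",
]


def candidate_distances(
    rgpn: nx.Graph, candidates: set[str], cutoff: int = 2
) -> dict[str, int]:
    """Min unweighted distance from each node to any candidate, up to ``cutoff``."""
    dist: dict[str, int] = {}
    for cand in sorted(candidates & set(rgpn.nodes)):
        for node, d in nx.single_source_shortest_path_length(
            rgpn, cand, cutoff=cutoff
        ).items():
            if d < dist.get(node, cutoff + 1):
                dist[node] = d
    return dist


def distance_component(rgpn: nx.Graph, node: str, candidates: set[str]) -> int:
    """Map the min candidate distance 0/1/2 to 4/2/1; 0 beyond two hops."""
    if node not in rgpn:
        raise LookupError_(f"node {node!r} absent from the RGPN")
    d = candidate_distances(rgpn, candidates).get(node)
    return DISTANCE_SCORES.get(d, 0)


# ---------------------------------------------------------------------------
# CAD/Tox expression component
# ---------------------------------------------------------------------------

def _minmax(s: pd.Series) -> pd.Series:
    lo, hi = s.min(), s.max()
    if hi == lo:
        return pd.Series(0.0, index=s.index)
    return (s - lo) / (hi - lo)


def _cad_tissue_summary(cad_panel: dict[str, ExpressionMatrix]) -> pd.DataFrame:
    """Per-gene per-tissue median log2 signal, arterial tissues merged."""
    med = pd.DataFrame(
        {t: m.values.median(axis=1) for t, m in cad_panel.items()}
    )
    arterial = [t for t in ("AAW", "IMA") if t in med.columns]
    if arterial:
        med["arterial"] = med[arterial].mean(axis=1)
        med = med.drop(columns=arterial)
    return med


def _tox_tissue_summary(tox_panel: dict[str, ExpressionMatrix]) -> pd.DataFrame:
    """Per-gene per-tissue FPKM with zero replacement, quality filtering
    and duplicate-row averaging."""
    cols = {}
    for t, m in tox_panel.items():
        vals = m.values.copy()
        vals[vals == 0.0] = FPKM_ZERO_REPLACEMENT
        if m.quality_tags is not None:
            keep = ~m.quality_tags.isin(["LOWDATA", "FAIL"])
            vals = vals.loc[keep[keep].index]
        summary = vals.median(axis=1)
        summary = summary.groupby(level=0).mean()  # duplicate gene rows -> mean
        cols[t] = summary
    return pd.DataFrame(cols)


def cad_tox_expression_score(
    cad_panel: dict[str, ExpressionMatrix],
    tox_panel: dict[str, ExpressionMatrix],
    reference_tissue_cad: str = "LIV",
    reference_tissue_tox: str = "liver",
    pseudocount: float = 0.01,
) -> pd.Series:
    """Per-gene expression component in [-2, 2].

    CAD side: per-tissue medians of the log2 values, the two arterial
    tissues averaged into one, each tissue divided by the liver median,
    mean over tissues (liver excluded, used only as divisor).  Tox side:
    zeros replaced by 0.5 FPKM, LOWDATA/FAIL genes removed, duplicates
    averaged, per-tissue value divided by liver, mean over tissues.  Each
    side is min-max transformed to [0, 1] across genes; for genes present
    on both sides the log2 CAD/Tox ratio (stabilised by a pseudocount) is
    linearly min-max scaled to [-2, 2].  Genes absent from either side
    are not in the returned series (treated as 0 on lookup).
    """
    if reference_tissue_cad not in cad_panel:
        raise ConfigurationError(
            f"cad_panel: missing reference (liver) tissue {reference_tissue_cad!r}"
        )
    if reference_tissue_tox not in tox_panel:
        raise ConfigurationError(
            f"tox_panel: missing reference (liver) tissue {reference_tissue_tox!r}"
        )
    cad = _cad_tissue_summary(
        {t: m for t, m in cad_panel.items() if t != reference_tissue_cad}
    )
    cad_liver = cad_panel[reference_tissue_cad].values.median(axis=1)
    cad_norm = cad.div(cad_liver, axis=0).mean(axis=1).dropna()

    tox = _tox_tissue_summary(
        {t: m for t, m in tox_panel.items() if t != reference_tissue_tox}
    )
    tox_liver_mat = tox_panel[reference_tissue_tox]
    tox_liver = _tox_tissue_summary({reference_tissue_tox: tox_liver_mat}).iloc[:, 0]
    tox_norm = tox.div(tox_liver, axis=0).mean(axis=1).dropna()

    cad01 = _minmax(cad_norm)
    tox01 = _minmax(tox_norm)
    common = cad01.index.intersection(tox01.index)
    ratio = np.log2(
        (cad01.loc[common] + pseudocount) / (tox01.loc[common] + pseudocount)
    )
    lo, hi = ratio.min(), ratio.max()
    if hi == lo:
        return pd.Series(0.0, index=common)
    return -2.0 + 4.0 * (ratio - lo) / (hi - lo)


def vascular_component(
    presence: pd.Series | dict[str, float] | None,
    threshold: float = VASCULAR_PRESENCE_THRESHOLD,
) -> int:
    """1 if the gene is MAS5-present in >=50% of samples of any vascular
    tissue, else 0; genes without presence data score 0."""
    if presence is None or len(presence) == 0:
        return 0
    values = pd.Series(presence).astype(float)
    return int(values.max() >= threshold)


def annotation_components(
    gene: str, bundle: AnnotationBundle
) -> tuple[int, int, int]:
    """(family, drug, mouse) components: 2/2/1 on membership, else 0."""
    family = 2 if gene in bundle.family_set else 0
    drug = 2 if gene in bundle.drug_targets else 0
    mouse = 1 if gene in bundle.mouse_set else 0
    return family, drug, mouse


def score_genes(
    rgpn: nx.Graph,
    candidates: set[str],
    expression_scores: pd.Series,
    bundle: AnnotationBundle,
) -> pd.DataFrame:
    """Six components plus the integrated sum for every node of an RGPN."""
    dist = candidate_distances(rgpn, candidates)
    vp = bundle.vascular_presence
    rows = []
    for node in sorted(rgpn.nodes):
        family, drug, mouse = annotation_components(node, bundle)
        presence = vp.loc[node] if vp is not None and node in vp.index else None
        row = dict(
            gene=node,
            distance_component=DISTANCE_SCORES.get(dist.get(node), 0),
            expression_component=float(expression_scores.get(node, 0.0)),
            vascular_component=vascular_component(presence),
            family_component=family,
            drug_component=drug,
            mouse_component=mouse,
        )
        row["integrated"] = float(sum(row[c] for c in COMPONENT_COLUMNS))
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", *COMPONENT_COLUMNS, "integrated"])


@dataclass
class ModuleFeasibility:
    """A module's mean integrated gene score (the CAD-feasibility score)."""

    module_id: str
    score: float
    size: int


def module_feasibility(
    module: Module, gene_scores: pd.DataFrame
) -> ModuleFeasibility:
    """Module score = sum of member integrated scores / module size."""
    if module.size == 0:
        raise ConfigurationError(f"module {module.module_id}: empty module")
    scores = gene_scores.set_index("gene")["integrated"]
    missing = module.nodes - set(scores.index)
    if missing:
        raise LookupError_(
            f"module {module.module_id}: unscored members {sorted(missing)[:5]}"
        )
    return ModuleFeasibility(
        module_id=module.module_id,
        score=float(scores.loc[sorted(module.nodes)].mean()),
        size=module.size,
    )
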