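"""TSV / GraphML / YAML readers and writers for all pipeline artifacts."""
from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .modules import Module
from .networks import CoexpressionNetwork, ExpressionMatrix

NETWORK_COLUMNS = ["network_id", "tissues", "node_a", "node_b"]


# -- expression -------------------------------------------------------------

def write_expression_panel(
    panel: dict[str, ExpressionMatrix], directory: Path, prefix: str
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tissue, mat in panel.items():
        out = mat.values.copy()
        if mat.quality_tags is not None:
            out.insert(0, "quality_tag", mat.quality_tags)
        safe = tissue.replace(" ", "_")
        out.rename_axis("gene").to_csv(
            directory / f"{prefix}_{safe}.tsv", sep="\t"
        )


def read_expression_panel(
    directory: Path, prefix: str, scale: str
) -> dict[str, ExpressionMatrix]:
    directory = Path(directory)
    panel: dict[str, ExpressionMatrix] = {}
    for path in sorted(directory.glob(f"{prefix}_*.tsv")):
        tissue = path.stem[len(prefix) + 1 :]
        if scale == "fpkm":
            tissue = tissue.replace("_", " ")  # CAD tissue codes have no spaces
        df = pd.read_csv(path, sep="\t", index_col="gene")
        tags = None
        if "quality_tag" in df.columns:
            tags = df.pop("quality_tag")
        panel[tissue] = ExpressionMatrix(
            tissue=tissue, scale=scale, values=df, quality_tags=tags
        )
    return panel


# -- co-expression networks -------------------------------------------------

def write_networks(networks: list[CoexpressionNetwork], path: Path) -> None:
    rows = [
        dict(
            network_id=net.network_id,
            tissues=";".join(net.tissues),
            node_a=a,
            node_b=b,
        )
        for net in networks
        for a, b in net.edges
    ]
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_networks(path: Path) -> list[CoexpressionNetwork]:
    df = pd.read_csv(path, sep="\t", dtype={"network_id": str})
    nets = []
    for nid, sub in df.groupby("network_id", sort=True):
        tissues = tuple(sub["tissues"].iloc[0].split(";"))
        edges = list(zip(sub["node_a"], sub["node_b"]))
        nets.append(CoexpressionNetwork(str(nid), tissues, edges))
    return nets


# -- RGPN graphs ------------------------------------------------------------

def write_rgpn(rgpn: nx.Graph, path: Path) -> None:
    g = rgpn.copy()
    g.graph["tissues"] = ";".join(g.graph.get("tissues", []))
    nx.write_graphml(g, path)


def read_rgpn(path: Path) -> nx.Graph:
    g = nx.read_graphml(path)
    g.graph["tissues"] = [t for t in g.graph.get("tissues", "").split(";") if t]
    g.graph["network_id"] = str(g.graph.get("network_id", Path(path).stem))
    return g


# -- modules ----------------------------------------------------------------

def write_modules(modules: list[Module], path: Path) -> None:
    rows = [
        dict(
            module_id=m.module_id,
            network_id=m.network_id,
            size=m.size,
            members=";".join(sorted(m.nodes)),
            candidate_members=";".join(sorted(m.contains_candidates)),
        )
        for m in modules
    ]
    pd.DataFrame(
        rows,
        columns=["module_id", "network_id", "size", "members", "candidate_members"],
    ).to_csv(path, sep="\t", index=False)


def read_modules(path: Path) -> list[Module]:
    df = pd.read_csv(
        path, sep="\t", dtype={"module_id": str, "network_id": str}
    )
    out = []
    for _, r in df.iterrows():
        cand = r.get("candidate_members")
        out.append(
            Module(
                module_id=r["module_id"],
                network_id=r["network_id"],
                nodes=set(str(r["members"]).split(";")),
                contains_candidates=(
                    set(str(cand).split(";")) if isinstance(cand, str) and cand else set()
                ),
            )
        )
    return out


# -- manifest ---------------------------------------------------------------

def write_manifest(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_manifest(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
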