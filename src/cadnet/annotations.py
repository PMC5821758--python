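"""Annotation sets used for gene feasibility scoring and enrichment.

The bundle collects the gene-level evidence that is external to the
expression networks: drug-gene interactions (DGIdb-style rows with a
cardiometabolic flag and a top-level ATC group per drug), the druggable
gene families (kinases and GPCRs, collapsed to unique symbols), mouse
atherosclerosis-phenotype genes, flat GO term -> gene annotations and
MAS5-style vascular presence-call fractions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import pandas as pd

#: The 14 top-level Anatomical Therapeutic Chemical groups.
ATC_GROUPS: dict[str, str] = {
    "A": "Alimentary tract and metabolism",
    "B": "Blood and blood-forming organs",
    "C": "Cardiovascular system",
    "D": "Dermatologicals",
    "G": "Genitourinary system and sex hormones",
    "H": "Systemic hormonal preparations, excluding sex hormones and insulins",
    "J": "Anti-infectives for systemic use",
    "L": "Antineoplastic and immunomodulating agents",
    "M": "Musculoskeletal system",
    "N": "Nervous system",
    "P": "Antiparasitic products, insecticides, and repellents",
    "R": "Respiratory system",
    "S": "Sensory organs",
    "V": "Various",
}

DRUG_COLUMNS = ["gene", "drug", "cardiometabolic", "atc"]


@dataclass
class AnnotationBundle:
    """Container for all gene-level annotation evidence.

    Parameters
    ----------
    drug_table
        One row per (gene, drug) interaction with columns
        ``gene, drug, cardiometabolic, atc``.  ``atc`` may be empty for
        drugs without a code; such drugs are excluded from ATC drug sets.
    family_set
        Kinase and GPCR coding genes collapsed to unique symbols.
    mouse_set
        Genes with a reported mouse atherosclerosis phenotype.
    go
        Flat GO annotations, term id -> gene set (no ontology propagation).
    vascular_presence
        Per-gene fraction of samples with a MAS5 "present" call, one
        column per vascular tissue (IMA, AAW).
    """

    drug_table: pd.DataFrame
    family_set: set[str] = field(default_factory=set)
    mouse_set: set[str] = field(default_factory=set)
    go: dict[str, set[str]] = field(default_factory=dict)
    vascular_presence: pd.DataFrame | None = None

    @cached_property
    def drug_targets(self) -> set[str]:
        """Genes with at least one drug interaction row."""
        return set(self.drug_table["gene"])

    @cached_property
    def cardiometabolic_targets(self) -> set[str]:
        """Genes targeted by one or more cardiometabolic drugs."""
        tab = self.drug_table
        return set(tab.loc[tab["cardiometabolic"].astype(bool), "gene"])

    @cached_property
    def other_drug_targets(self) -> set[str]:
        """Drug-targeted genes with no cardiometabolic drug."""
        return self.drug_targets - self.cardiometabolic_targets

    def atc_sets(self) -> dict[str, set[str]]:
        """Gene sets targeted by >=1 drug of each top-level ATC group.

        Drugs without an ATC code are excluded.  A gene targeted by drugs
        of several groups belongs to each of those group sets.
        """
        tab = self.drug_table
        out: dict[str, set[str]] = {code: set() for code in ATC_GROUPS}
        for _, row in tab.iterrows():
            code = str(row["atc"]) if pd.notna(row["atc"]) else ""
            if code in out:
                out[code].add(row["gene"])
        return out

    # -- persistence -------------------------------------------------
    def write(self, directory: Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.drug_table.to_csv(directory / "drugs.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": sorted(self.family_set)}).to_csv(
            directory / "family.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene": sorted(self.mouse_set)}).to_csv(
            directory / "mouse.tsv", sep="\t", index=False
        )
        rows = [
            {"term": term, "gene": g}
            for term, genes in sorted(self.go.items())
            for g in sorted(genes)
        ]
        pd.DataFrame(rows, columns=["term", "gene"]).to_csv(
            directory / "go.tsv", sep="\t", index=False
        )
        if self.vascular_presence is not None:
            self.vascular_presence.rename_axis("gene").to_csv(
                directory / "vascular_presence.tsv", sep="\t"
            )

    @classmethod
    def read(cls, directory: Path) -> "AnnotationBundle":
        directory = Path(directory)
        drug_table = pd.read_csv(
            directory / "drugs.tsv", sep="\t", dtype={"atc": str}
        )
        family = set(pd.read_csv(directory / "family.tsv", sep="\t")["gene"])
        mouse = set(pd.read_csv(directory / "mouse.tsv", sep="\t")["gene"])
        go_tab = pd.read_csv(directory / "go.tsv", sep="\t")
        go = {
            term: set(sub["gene"])
            for term, sub in go_tab.groupby("term")
        }
        vp_path = directory / "vascular_presence.tsv"
        vascular = (
            pd.read_csv(vp_path, sep="\t", index_col="gene")
            if vp_path.exists()
            else None
        )
        return cls(drug_table, family, mouse, go, vascular)
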