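"""Over-representation statistics for modules.

All tests are right-tail Fisher exact tests on 2x2 tables (enrichment
only).  GO term tests are Benjamini-Hochberg corrected per module; the
ATC drug-set tests are reported at raw right-tail P < 0.05; the drug
tests (overall drug targets, and cardiometabolic vs other targets
within the drug-targeted sub-universe) are reported raw.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotations import ATC_GROUPS, AnnotationBundle

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """A 2x2 overlap test: counts, odds ratio, right-tail p and BH q."""

    unit: str
    table: tuple[int, int, int, int]  # (in&set, in-set, out&set, out-set)
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def fisher_right_tail(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Right-tail Fisher exact test on the table [[a, b], [c, d]].

    ``a`` is the observed overlap (in-module and in-set), ``b`` the
    module members outside the set, ``c`` the set members outside the
    module, ``d`` the rest of the universe.  The p-value is the
    hypergeometric upper tail P(X >= a); the odds ratio is a*d/(b*c),
    infinity when b*c = 0 with a*d > 0, and 1 for the degenerate
    all-zero table (p = 1).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0, 1.0
    n_set = a + c
    n_draw = a + b
    p = float(hypergeom.sf(a - 1, n_total, n_set, n_draw))
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 1.0
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values, order-preserving, clipped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _overlap_test(unit: str, members: set, gene_set: set, universe: set) -> EnrichmentResult:
    a = len(members & gene_set)
    b = len(members - gene_set)
    c = len((universe - members) & gene_set)
    d = len(universe - members - gene_set)
    odds, p = fisher_right_tail(a, b, c, d)
    return EnrichmentResult(unit=unit, table=(a, b, c, d), odds_ratio=odds, p_value=p)


def go_enrichment(
    module_nodes: set[str],
    go: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Per-term right-tail Fisher tests with BH correction across terms.

    Module genes missing from the universe are added to it (with a
    warning) so counts stay consistent.  Terms with no universe gene are
    skipped.
    """
    missing = module_nodes - universe
    if missing:
        log.warning(
            "%d module genes absent from universe; adding them", len(missing)
        )
        universe = universe | missing
    results = []
    for term in sorted(go):
        genes = go[term] & universe
        if not genes:
            continue
        results.append(_overlap_test(term, module_nodes, genes, universe))
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def main_go_term(results: list[EnrichmentResult]) -> EnrichmentResult | None:
    """Headline term: minimum q, ties to the larger overlap, then lexicographic."""
    if not results:
        return None
    return min(results, key=lambda r: (r.q_value, -r.table[0], r.unit))


def drug_enrichment(
    module_nodes: set[str],
    bundle: AnnotationBundle,
    universe: set[str],
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Overall drug-target enrichment and the cardiometabolic contrast.

    The overall test compares the module's drug-targeted members with
    all drug-targeted genes over the network universe.  The
    cardiometabolic test restricts the universe to drug-targeted genes
    and asks whether the module's targeted members are enriched for
    genes hit by >=1 cardiometabolic drug (vs only other drugs).
    """
    targets = bundle.drug_targets & universe
    overall = _overlap_test("drug_targets", module_nodes & universe, targets, universe)
    module_targets = module_nodes & targets
    if not module_targets:
        cardio = EnrichmentResult(
            unit="cardiometabolic", table=(0, 0, 0, 0), odds_ratio=1.0, p_value=1.0
        )
    else:
        cm = bundle.cardiometabolic_targets & targets
        cardio = _overlap_test("cardiometabolic", module_targets, cm, targets)
    return overall, cardio


def atc_enrichment(
    module_nodes: set[str],
    bundle: AnnotationBundle,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-ATC-group drug-set enrichment at raw right-tail P < alpha.

    The drug set of a group is every gene targeted by >=1 drug carrying
    that top-level code; the background is the drug-targeted universe.
    Drugs without an ATC code never enter a set.  No multiple-testing
    correction is applied, matching the raw-p convention for drug sets.
    """
    targets = bundle.drug_targets if universe is None else bundle.drug_targets & universe
    atc_sets = bundle.atc_sets()
    rows = []
    for code in sorted(ATC_GROUPS):
        gene_set = atc_sets[code] & targets
        res = _overlap_test(code, module_nodes & targets, gene_set, targets)
        rows.append(
            dict(
                atc_code=code,
                atc_group=ATC_GROUPS[code],
                overlap=res.table[0],
                set_size=len(gene_set),
                odds_ratio=res.odds_ratio,
                p_value=res.p_value,
                significant=res.p_value < alpha,
            )
        )
    return pd.DataFrame(rows)
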