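"""Score-validation statistics: quintile split, drug-target fractions,
Kolmogorov-Smirnov group contrasts and the top-module subgroup.

Modules are ranked by CAD-feasibility score and divided into five
near-equal groups (the larger blocks at the top of the ranking), plus a
TOP group of the highest-scoring modules (a subgroup of the 5th
quintile).  For each module the percentage of nodes targeted by
cardiometabolic drugs and the ratio of cardiometabolic to other drug
targets are computed; group differences are assessed with the
two-sample Kolmogorov-Smirnov test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .annotations import AnnotationBundle
from .errors import ConfigurationError

log = logging.getLogger(__name__)

DEFAULT_RATIO_CAP = 10.0
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class ValidationGroup:
    """A score-rank group of modules with its per-module statistics."""

    label: str  # Q1..Q5 or TOP
    module_ids: list[str]
    fraction_values: list[float] = field(default_factory=list)
    ratio_values: list[float] = field(default_factory=list)

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fraction_values)) if self.fraction_values else float("nan")

    @property
    def sd_fraction(self) -> float:
        return float(np.std(self.fraction_values, ddof=1)) if len(self.fraction_values) > 1 else float("nan")

    @property
    def mean_ratio(self) -> float:
        return float(np.mean(self.ratio_values)) if self.ratio_values else float("nan")

    @property
    def sd_ratio(self) -> float:
        return float(np.std(self.ratio_values, ddof=1)) if len(self.ratio_values) > 1 else float("nan")


def quintile_split(
    module_scores: pd.DataFrame,
    n_groups: int = 5,
    top_n: int = 25,
) -> list[ValidationGroup]:
    """Rank modules by score (descending) into near-equal groups plus TOP.

    ``module_scores`` needs columns ``module_id`` and ``score``.  Group
    sizes differ by at most one, with the larger blocks at the top of the
    ranking; score ties at a boundary are broken by module_id so the
    split is deterministic.  Returns groups labelled Q5 (top) down to Q1,
    followed by the TOP group of the ``top_n`` highest-scoring modules.
    """
    n = len(module_scores)
    if n < n_groups:
        raise ConfigurationError(
            f"module_scores: need >= {n_groups} modules, got {n}"
        )
    ranked = module_scores.sort_values(
        ["score", "module_id"], ascending=[False, True]
    ).reset_index(drop=True)
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if i < extra else 0) for i in range(n_groups)]
    groups: list[ValidationGroup] = []
    pos = 0
    for i, size in enumerate(sizes):
        label = f"Q{n_groups - i}"
        ids = list(ranked["module_id"].iloc[pos : pos + size])
        groups.append(ValidationGroup(label=label, module_ids=ids))
        pos += size
    groups = groups[::-1]  # report Q1..Q5
    top_ids = list(ranked["module_id"].iloc[: min(top_n, n)])
    groups.append(ValidationGroup(label="TOP", module_ids=top_ids))
    return groups


def module_drug_fractions(
    members: set[str],
    bundle: AnnotationBundle,
    ratio_cap: float = DEFAULT_RATIO_CAP,
) -> tuple[float, float]:
    """(% of nodes targeted by cardiometabolic drugs, cardio/other ratio).

    A zero denominator with a nonzero numerator is capped at
    ``ratio_cap``; 0/0 is reported as 0.
    """
    if not members:
        return 0.0, 0.0
    n_cm = len(members & bundle.cardiometabolic_targets)
    n_other = len(members & bundle.other_drug_targets)
    fraction = 100.0 * n_cm / len(members)
    if n_other == 0:
        ratio = 0.0 if n_cm == 0 else ratio_cap
        if n_cm:
            log.debug("ratio capped at %.1f (%d cardiometabolic, 0 other)", ratio_cap, n_cm)
    else:
        ratio = min(n_cm / n_other, ratio_cap)
    return fraction, ratio


def ks_two_group(
    sample_a, sample_b, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sided two-sample KS test: D = sup |ECDF_a - ECDF_b| and its p.

    Asymptotic p by default; pass ``method='exact'`` for the small-sample
    exact distribution.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("samples: both KS samples must be nonempty")
    res = ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fill_group_statistics(
    groups: list[ValidationGroup],
    module_members: dict[str, set[str]],
    bundle: AnnotationBundle,
    ratio_cap: float = DEFAULT_RATIO_CAP,
) -> None:
    """Populate per-module fraction/ratio values for each group in place."""
    for g in groups:
        g.fraction_values = []
        g.ratio_values = []
        for mid in g.module_ids:
            frac, ratio = module_drug_fractions(
                module_members[mid], bundle, ratio_cap
            )
            g.fraction_values.append(frac)
            g.ratio_values.append(ratio)


def stars(p: float) -> str:
    for threshold, symbol in STAR_THRESHOLDS:
        if p < threshold:
            return symbol
    return ""


def validation_report(
    groups: list[ValidationGroup], method: str = "asymp"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summary table and all pairwise KS contrasts with stars.

    Returns ``(summary, pairwise)``: per-group mean +/- sd of the
    cardiometabolic-target fraction and ratio, and for every group pair
    the KS D, p-value and significance stars on both statistics.
    """
    summary = pd.DataFrame(
        [
            dict(
                group=g.label,
                n_modules=len(g.module_ids),
                mean_fraction=g.mean_fraction,
                sd_fraction=g.sd_fraction,
                mean_ratio=g.mean_ratio,
                sd_ratio=g.sd_ratio,
            )
            for g in groups
        ]
    )
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            if not a.fraction_values or not b.fraction_values:
                continue
            d_f, p_f = ks_two_group(a.fraction_values, b.fraction_values, method)
            d_r, p_r = ks_two_group(a.ratio_values, b.ratio_values, method)
            rows.append(
                dict(
                    group_a=a.label,
                    group_b=b.label,
                    ks_d_fraction=d_f,
                    p_fraction=p_f,
                    stars_fraction=stars(p_f),
                    ks_d_ratio=d_r,
                    p_ratio=p_r,
                    stars_ratio=stars(p_r),
                )
            )
    return summary, pd.DataFrame(rows)
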