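"""Tissue-cohort integration and small-sample statistics.

Overlap of a pulldown-derived target list with a tissue differential
expression table (hypergeometric enrichment), the Pearson chi-square test
on a 2x2 contingency table, percentage summaries, the caliper
tumor-volume formula and the unpaired two-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "overlap_tissue",
    "pearson_chi2",
    "proportion_summary",
    "tumor_volume",
    "two_sided_t_test",
]


@dataclass(frozen=True)
class OverlapResult:
    """Summary of the target-list vs tissue-downregulated-set overlap."""

    n_targets: int
    n_tissue_down: int
    n_overlap: int
    mean_fold_down: float  # geometric mean fold-down of overlapping genes
    hypergeom_p: float


def overlap_tissue(
    targets,
    tissue_table: pd.DataFrame,
    universe_size: int,
    down_fold_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
) -> OverlapResult:
    """Overlap a target list with the tissue-downregulated gene set.

    ``tissue_table`` needs columns ``gene_id``, ``log2fc`` (tumor vs
    benign) and ``p``.  The tissue-down set is genes downregulated at
    least ``down_fold_cutoff``-fold (log2fc <= -log2 cutoff) at
    ``p <= p_cutoff``.  Enrichment is the upper hypergeometric tail of the
    overlap when ``n_targets`` genes are drawn from a universe of
    ``universe_size`` containing the tissue-down set.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("target list is empty")
    table = tissue_table.set_index("gene_id")
    missing = set(targets) - set(table.index)
    if missing:
        raise ValueError(f"targets missing from tissue table: {sorted(missing)[:3]}")
    if universe_size < len(table):
        raise ValueError("universe_size must be at least the tissue table size")

    down = table[(table["log2fc"] <= -np.log2(down_fold_cutoff)) & (table["p"] <= p_cutoff)]
    overlap = down.loc[down.index.intersection(targets)]
    k = len(overlap)
    mean_fold = float(2.0 ** (-overlap["log2fc"].mean())) if k else float("nan")
    p = float(
        stats.hypergeom.sf(k - 1, universe_size, len(down), len(targets))
    )
    return OverlapResult(
        n_targets=len(targets),
        n_tissue_down=len(down),
        n_overlap=k,
        mean_fold_down=mean_fold,
        hypergeom_p=p,
    )


def pearson_chi2(
    a: int, b: int, c: int, d: int, continuity_correction: bool = False
) -> tuple[float, float]:
    """Two-sided Pearson chi-square test on a 2x2 contingency table.

    The table is ``[[a, b], [c, d]]`` (rows = outcome group, columns =
    marker status).  Statistic ``n (|ad - bc| - corr)^2 / ((a+b)(c+d)(a+c)(b+d))``
    with ``corr = n/2`` under the Yates continuity correction (off by
    default), referred to chi-square with 1 df.  A zero marginal yields
    statistic 0 and p 1 with a warning.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("contingency cells must be non-negative")
    n = cells.sum()
    if n < 1:
        raise ValueError("table total must be at least 1")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        warnings.warn("2x2 table has a zero marginal; chi-square undefined, returning 0")
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    statistic = n * diff**2 / denom
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def proportion_summary(positive: int, total: int) -> float:
    """Percentage ``100 * positive / total`` rounded half-up to 1 decimal."""
    if total < 1:
        raise ValueError("total must be at least 1")
    if not 0 <= positive <= total:
        raise ValueError("positive must lie in [0, total]")
    pct = Decimal(100 * positive) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tumor_volume(length_a: float, width_b: float) -> float:
    """Caliper tumor volume ``(a * b^2) / 2`` in mm^3.

    ``length_a`` is the largest dimension, ``width_b`` the smallest
    dimension perpendicular to it; the call is rejected if the convention
    is violated.
    """
    if width_b <= 0:
        raise ValueError("width_b must be positive")
    if width_b > length_a:
        raise ValueError(
            "width_b exceeds length_a: by convention the length (a) is the "
            "largest dimension and the width (b) the smallest"
        )
    return float(length_a * width_b**2 / 2.0)


def two_sided_t_test(group1, group2, equal_var: bool = True) -> float:
    """Two-sided unpaired t-test p-value (Student by default, Welch option)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least two values")
    if np.var(g1) == 0 and np.var(g2) == 0 and g1.mean() == g2.mean():
        return 1.0
    return float(stats.ttest_ind(g1, g2, equal_var=equal_var).pvalue)
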