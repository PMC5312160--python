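"""Target definition and prioritization rules.

A gene is a *potential* direct target of the overexpressed microRNA when
it is enriched in the Argonaute pulldown relative to both background
fractions and simultaneously repressed in the lysate:

    log2FC(Ago-IP_IgG) > 0  and  log2FC(Ago-IP_TL) > 0  and
    log2FC(lysate) < 0

Prioritized targets must additionally be enriched at least 4-fold in the
Ago-IP fractions, downregulated at least 1.5-fold in the lysate, and be
expressed at >= 8 counts per million in every library (the thresholds are
inclusive and configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import CELL_ORDER

__all__ = [
    "ContrastSpec",
    "builtin_contrasts",
    "call_potential_targets",
    "prioritize_targets",
    "AGO_IGG",
    "AGO_TL",
    "LYSATE",
]

AGO_IGG = "Ago-IP_IgG"
AGO_TL = "Ago-IP_TL"
LYSATE = "lysate"


@dataclass(frozen=True)
class ContrastSpec:
    """A named linear combination over the six cell means.

    Coefficients follow :data:`agoripseq.glm.CELL_ORDER`; they must sum to
    zero and not all vanish.
    """

    name: str
    coefficients: tuple

    def __post_init__(self):
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (len(CELL_ORDER),):
            raise ValueError(f"contrast must have {len(CELL_ORDER)} coefficients")
        if abs(coefs.sum()) > 1e-12:
            raise ValueError("contrast coefficients must sum to zero")
        if np.all(coefs == 0):
            raise ValueError("contrast must not be all zeros")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in coefs))


def builtin_contrasts() -> list[ContrastSpec]:
    """The three background-correcting comparisons of the factorial design.

    - ``Ago-IP_IgG``: (Ago.miR − IgG.miR) − (Ago.control − IgG.control) —
      Ago enrichment adjusted for nonspecific bead/antibody binding.
    - ``Ago-IP_TL``: (Ago.miR − TL.miR) − (Ago.control − TL.control) —
      Ago enrichment adjusted for secondary transcriptome changes.
    - ``lysate``: TL.miR − TL.control — plain expression response to the
      overexpression.
    """
    # coefficient order: Ago.miR, IgG.miR, TL.miR, Ago.control, IgG.control, TL.control
    return [
        ContrastSpec(AGO_IGG, (1, -1, 0, -1, 1, 0)),
        ContrastSpec(AGO_TL, (1, 0, -1, -1, 0, 1)),
        ContrastSpec(LYSATE, (0, 0, 1, 0, 0, -1)),
    ]


def _aligned(results: dict, name: str, genes: np.ndarray) -> pd.DataFrame:
    if name not in results:
        raise ValueError(f"missing contrast results for {name!r}")
    r = results[name].set_index("gene_id")
    if set(r.index) != set(genes):
        raise ValueError(f"gene universe mismatch in contrast {name!r}")
    return r.loc[genes]

def call_potential_targets(
    results: dict[str, pd.DataFrame],
    fdr_cutoff: float | None = None,
    fdr_contrasts: tuple[str, ...] = (AGO_IGG, AGO_TL),
) -> pd.DataFrame:
    """Apply the sign rule over the three contrast result tables.

    ``results`` maps contrast names to per-gene tables with at least
    ``gene_id``, ``log2fc`` and ``fdr`` columns, all covering the same
    genes.  With ``fdr_cutoff`` set, a gene must additionally reach
    ``fdr <= cutoff`` in each contrast named by ``fdr_contrasts`` (an
    optional stringency extension, off by default; the default gate is the
    two Ago-enrichment contrasts — a modest lysate repression is rarely
    individually significant at 3 vs 3 replicates and contributes its sign
    only).
    """
    genes = results[AGO_IGG]["gene_id"].to_numpy() if AGO_IGG in results else None
    if genes is None:
        raise ValueError(f"missing contrast results for {AGO_IGG!r}")
    igg = _aligned(results, AGO_IGG, genes)
    tl = _aligned(results, AGO_TL, genes)
    lys = _aligned(results, LYSATE, genes)

    potential = (
        (igg["log2fc"].to_numpy() > 0)
        & (tl["log2fc"].to_numpy() > 0)
        & (lys["log2fc"].to_numpy() < 0)
    )
    if fdr_cutoff is not None:
        frames = {AGO_IGG: igg, AGO_TL: tl, LYSATE: lys}
        unknown = set(fdr_contrasts) - set(frames)
        if unknown:
            raise ValueError(f"unknown contrast(s) in fdr_contrasts: {sorted(unknown)}")
        for name in fdr_contrasts:
            potential &= frames[name]["fdr"].to_numpy() <= fdr_cutoff
    return pd.DataFrame(
        {
            "gene_id": genes,
            "is_potential_target": potential,
            "is_prioritized": False,
            "log2fc_ago_igg": igg["log2fc"].to_numpy(),
            "log2fc_ago_tl": tl["log2fc"].to_numpy(),
            "log2fc_lysate": lys["log2fc"].to_numpy(),
            "fdr_ago_igg": igg["fdr"].to_numpy(),
            "fdr_ago_tl": tl["fdr"].to_numpy(),
            "fdr_lysate": lys["fdr"].to_numpy(),
        }
    )


def prioritize_targets(
    calls: pd.DataFrame,
    cpm_matrix: pd.DataFrame,
    min_ago_fold: float = 4.0,
    min_lysate_fold: float = 1.5,
    min_cpm: float = 8.0,
    ago_rule: str = "both",
) -> pd.DataFrame:
    """Flag prioritized targets among the potential ones.

    A potential target is prioritized when its estimated Ago enrichment is
    at least ``min_ago_fold`` (in both Ago contrasts by default, per the
    plural "fractions"; set ``ago_rule='any'`` for the single-contrast
    variant), its lysate repression at least ``min_lysate_fold``, and its
    expression at least ``min_cpm`` counts per million in every library.
    All thresholds are inclusive.  ``cpm_matrix`` is genes x libraries.
    """
    if min_ago_fold <= 0 or min_lysate_fold <= 0 or min_cpm < 0:
        raise ValueError("fold thresholds must be positive and min_cpm non-negative")
    missing = set(calls["gene_id"]) - set(cpm_matrix.index)
    if missing:
        raise ValueError(f"CPM matrix missing {len(missing)} gene(s), e.g. {sorted(missing)[:3]}")
    out = calls.copy()
    cpm_min = cpm_matrix.loc[out["gene_id"], :].min(axis=1).to_numpy()
    out["min_cpm"] = cpm_min

    ago_thr = np.log2(min_ago_fold)
    lys_thr = -np.log2(min_lysate_fold)
    igg_ok = out["log2fc_ago_igg"].to_numpy() >= ago_thr
    tl_ok = out["log2fc_ago_tl"].to_numpy() >= ago_thr
    if ago_rule == "both":
        ago_ok = igg_ok & tl_ok
    elif ago_rule == "any":
        ago_ok = igg_ok | tl_ok
    else:
        raise ValueError("ago_rule must be 'both' or 'any'")
    out["is_prioritized"] = (
        out["is_potential_target"].to_numpy()
        & ago_ok
        & (out["log2fc_lysate"].to_numpy() <= lys_thr)
        & (cpm_min >= min_cpm)
    )
    return out
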