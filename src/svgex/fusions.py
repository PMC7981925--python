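"""Corroborating RNA-seq fusion candidates with WGS SV breakpoints.

A fusion candidate (5' gene, 3' gene, sample) gains SV support when the
same sample carries a breakpoint inside one or both gene bodies.  A
"high expression association" flag is added from either of two rules:

1. for fusions seen in at most two samples, every harbouring sample
   over-expresses at least one partner (> 0.4 cross-sample SD above the
   partner's cross-sample median); or
2. either partner shows a significant positive breakpoint-expression
   association (p < 0.01, cancer-type + CNA model) in the
   distance-weighted 1 Mb window or the gene-body window.

Recurrence is counted on the unordered gene pair; the 5'/3' order is
kept for reporting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .association import (
    MODEL_TYPE_PLUS_CNA,
    STATUS_OK,
    overexpression_flags,
)
from .model import Config, GeneModel, RegionWindow, SvRecord

logger = logging.getLogger(__name__)

SUPPORT_NONE = "none"
SUPPORT_ONE = "sv_one_gene"
SUPPORT_BOTH = "sv_both_genes"


def _body_hits(genes_by_id: dict[str, GeneModel], svs: list[SvRecord]) -> set[tuple[str, str]]:
    """(gene_id, sample_id) pairs with a breakpoint inside the gene body."""
    hits: set[tuple[str, str]] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes_by_id.values():
        by_chrom.setdefault(g.chrom, []).append(g)
    for sv in svs:
        for bp in sv.breakpoints:
            for g in by_chrom.get(bp.chrom, ()):
                if g.start <= bp.pos < g.end:
                    hits.add((g.gene_id, bp.sample_id))
    return hits


def annotate_sv_support(
    fusions: pd.DataFrame, genes: list[GeneModel], svs: list[SvRecord]
) -> pd.DataFrame:
    """Add ``support`` and ``n_samples_with_fusion`` columns.

    ``fusions`` needs gene5, gene3, sample columns.  Partners missing from
    the gene table are logged and contribute no support; recurrence counts
    samples per unordered gene pair.
    """
    required = {"gene5", "gene3", "sample"}
    if not required <= set(fusions.columns):
        raise ValueError(f"fusion table needs columns {sorted(required)}")
    genes_by_id = {g.gene_id: g for g in genes}
    missing = (set(fusions["gene5"]) | set(fusions["gene3"])) - set(genes_by_id)
    if missing:
        logger.warning(
            "%d fusion partner gene(s) absent from the gene table; "
            "support computed on the available partner only",
            len(missing),
        )
    hits = _body_hits(genes_by_id, svs)
    out = fusions.copy()
    support = []
    for r in out.itertuples(index=False):
        in5 = (r.gene5, r.sample) in hits
        in3 = (r.gene3, r.sample) in hits
        support.append(
            SUPPORT_BOTH if (in5 and in3) else SUPPORT_ONE if (in5 or in3) else SUPPORT_NONE
        )
    out["support"] = support
    pair = out.apply(lambda r: tuple(sorted((r["gene5"], r["gene3"]))), axis=1)
    n_per_pair = (
        pd.DataFrame({"pair": pair, "sample": out["sample"]})
        .groupby("pair")["sample"]
        .nunique()
    )
    out["n_samples_with_fusion"] = pair.map(n_per_pair).astype(int)
    return out


def annotate_high_expression(
    fusions: pd.DataFrame,
    expr_matrix: pd.DataFrame,
    assoc_results: pd.DataFrame,
    config: Config | None = None,
) -> pd.DataFrame:
    """Add the ``high_expression`` flag (rule 1 OR rule 2, see module doc).

    ``assoc_results`` is the screen table from
    :func:`svgex.association.run_association_screen` and must contain the
    CNA-corrected family for the distance-weighted 1 Mb and gene-body
    windows.
    """
    config = config or Config()
    if "n_samples_with_fusion" not in fusions.columns:
        raise ValueError("run annotate_sv_support first")
    over = overexpression_flags(expr_matrix, config.overexpr_sd_threshold)

    qualifying = assoc_results[
        (assoc_results["model"] == MODEL_TYPE_PLUS_CNA)
        & (assoc_results["status"] == STATUS_OK)
        & (assoc_results["window"].isin(
            [RegionWindow.FLANK_1MB.value, RegionWindow.GENE_BODY.value]
        ))
        & (assoc_results["p_value"] < config.fusion_p_threshold)
        & (assoc_results["t_stat"] > 0)
    ]
    sig_genes = set(qualifying["gene_id"])

    def rule1(r) -> bool:
        if r["n_samples_with_fusion"] > 2:
            return False
        harbouring = fusions.loc[
            (fusions["gene5"] == r["gene5"]) & (fusions["gene3"] == r["gene3"]),
            "sample",
        ].unique()
        for s in harbouring:
            sample_over = False
            for g in (r["gene5"], r["gene3"]):
                if g in over.index and s in over.columns and bool(over.at[g, s]):
                    sample_over = True
                    break
            if not sample_over:
                return False
        return True

    def rule2(r) -> bool:
        return r["gene5"] in sig_genes or r["gene3"] in sig_genes

    out = fusions.copy()
    out["high_expression"] = [
        bool(rule1(r) or rule2(r)) for _, r in out.iterrows()
    ]
    return out


def support_summary(fusions: pd.DataFrame) -> dict[str, float]:
    """Counts of the nested support tiers over annotated candidates."""
    n = len(fusions)
    n_sv = int((fusions["support"] != SUPPORT_NONE).sum())
    n_sv_hi = int(
        ((fusions["support"] != SUPPORT_NONE) & fusions["high_expression"]).sum()
    )
    return {
        "n_candidates": n,
        "n_sv_support": n_sv,
        "n_sv_support_high_expression": n_sv_hi,
        "frac_sv_support": n_sv / n if n else np.nan,
    }
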