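"""Calibration and recovery metrics on synthetic cohorts.

Convenience layer tying the simulator to the screen: run the standard
screen on a cohort, measure planted-effect recovery against the truth
table, measure type-I error on null cohorts, and compute the mechanism
enrichment statistics (enhancer hijack, TAD disruption) end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import (
    MODEL_TYPE_ONLY,
    MODEL_TYPE_PLUS_CNA,
    STATUS_OK,
    run_association_screen,
)
from .hijack import call_hijacks, hijack_enrichment
from .matrix import build_matrix, gene_sv_associations
from .model import Config, RegionWindow
from .pipeline import overexpressed_pairs
from .simulate import Cohort
from .tads import classify_all, tad_enrichment


def screen_cohort(
    cohort: Cohort,
    window: RegionWindow = RegionWindow.FLANK_1MB,
    weighted: bool = False,
    with_cna: bool = True,
    config: Config | None = None,
) -> pd.DataFrame:
    """Run the association screen on a simulated cohort (one window)."""
    config = config or Config()
    bpm = build_matrix(
        cohort.genes, cohort.svs, window, config,
        samples=cohort.samples, weighted=weighted,
    )
    return run_association_screen(
        cohort.expr,
        bpm,
        cohort.sample_annotation,
        cohort.cna if with_cna else None,
        config,
    )


def _family(screen: pd.DataFrame, window: RegionWindow, model: str) -> pd.DataFrame:
    return screen[
        (screen["window"] == window.value)
        & (screen["model"] == model)
        & (screen["status"] == STATUS_OK)
    ]


def type1_error(
    screen: pd.DataFrame,
    alpha: float = 0.05,
    window: RegionWindow = RegionWindow.FLANK_1MB,
    model: str = MODEL_TYPE_PLUS_CNA,
) -> float:
    """Fraction of fitted genes with p < alpha (on a null cohort, the
    empirical type-I error)."""
    fam = _family(screen, window, model)
    return float((fam["p_value"] < alpha).mean())


def effect_recovery(
    cohort: Cohort,
    screen: pd.DataFrame,
    window: RegionWindow = RegionWindow.FLANK_1MB,
    model: str = MODEL_TYPE_PLUS_CNA,
    fdr: float = 0.10,
) -> dict[str, float]:
    """Sensitivity and sign agreement for planted effect genes.

    A planted gene counts as recovered when its q-value beats ``fdr`` and
    the t-statistic has the planted sign (positive here: planted shifts
    increase expression).
    """
    fam = _family(screen, window, model).set_index("gene_id")
    truth_genes = cohort.truth.loc[cohort.truth["has_effect"], "gene_id"]
    n_recovered = 0
    n_sign_ok = 0
    for g in truth_genes:
        if g in fam.index:
            row = fam.loc[g]
            if row["q_value"] < fdr:
                n_recovered += 1
                if row["t_stat"] > 0:
                    n_sign_ok += 1
    n_truth = len(truth_genes)
    return {
        "n_effect_genes": n_truth,
        "sensitivity": n_recovered / n_truth if n_truth else np.nan,
        "sensitivity_sign_correct": n_sign_ok / n_truth if n_truth else np.nan,
    }


def mechanism_enrichment(
    cohort: Cohort,
    screen: pd.DataFrame | None = None,
    config: Config | None = None,
) -> dict:
    """Hijack and TAD enrichment p-values for a cohort, end to end.

    Over-expressed (gene, sample) pairs are screen-significant genes
    (CNA-corrected 1 Mb family) whose harbouring sample exceeds the 0.4 SD
    rule; hijack enrichment compares event rates over the distal-mate
    association calls, TAD enrichment compares disruption rates over the
    classified SVs linked to those pairs.
    """
    config = config or Config()
    if screen is None:
        screen = screen_cohort(cohort, weighted=True, config=config)
    over = overexpressed_pairs(screen, cohort.expr, config)
    assocs = gene_sv_associations(cohort.genes, cohort.svs, RegionWindow.FLANK_1MB, config)
    calls = call_hijacks(assocs, cohort.genes, cohort.svs, cohort.enhancers, config)
    hijack_table, hijack_p = hijack_enrichment(calls, over)
    tad_calls = classify_all(cohort.svs, cohort.tads)
    tad_table, tad_p = tad_enrichment(tad_calls, assocs, over)
    return {
        "n_overexpressed_pairs": len(over),
        "n_hijack_calls": len(calls),
        "n_hijack_events": int(sum(c.is_event for c in calls)),
        "hijack_table": hijack_table,
        "hijack_p": hijack_p,
        "tad_table": tad_table,
        "tad_p": tad_p,
    }


def n_significant(
    screen: pd.DataFrame,
    window: RegionWindow = RegionWindow.FLANK_1MB,
    model: str = MODEL_TYPE_ONLY,
    fdr: float = 0.10,
) -> int:
    fam = _family(screen, window, model)
    return int((fam["q_value"] < fdr).sum())
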