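"""TAD-preserving vs TAD-disrupting classification of SVs.

An SV is TAD-preserving when both breakpoints fall inside the same
topologically associated domain, and TAD-disrupting when they fall in
different domains (including different chromosomes), i.e. the
rearrangement spans at least one boundary.  Real TAD annotations have
gaps and nested calls: a breakpoint in a gap leaves the SV unassigned,
and a breakpoint inside nested TADs is resolved to the smallest
(most specific) containing domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .association import chisq_2x2
from .model import SvRecord

CLASS_PRESERVING = "preserving"
CLASS_DISRUPTING = "disrupting"
CLASS_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TadCall:
    sv_id: str
    sample_id: str
    tad_class: str
    tad1: tuple[str, int, int] | None
    tad2: tuple[str, int, int] | None


class TadIndex:
    """Interval index over TADs; containment resolves to the smallest TAD."""

    def __init__(self, tads: pd.DataFrame):
        self._trees: dict[str, IntervalTree] = {}
        for r in tads.itertuples(index=False):
            self._trees.setdefault(str(r.chrom), IntervalTree()).addi(
                int(r.start), int(r.end)
            )

    def assign(self, chrom: str, pos: int) -> tuple[str, int, int] | None:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree.at(pos)
        if not hits:
            return None
        best = min(hits, key=lambda iv: (iv.end - iv.begin, iv.begin))
        return (chrom, best.begin, best.end)


def classify_sv_tad(sv: SvRecord, tads: pd.DataFrame | TadIndex) -> TadCall:
    """Classify one SV as preserving / disrupting / unassigned."""
    index = tads if isinstance(tads, TadIndex) else TadIndex(tads)
    tad1 = index.assign(sv.bp1.chrom, sv.bp1.pos)
    tad2 = index.assign(sv.bp2.chrom, sv.bp2.pos)
    if tad1 is None or tad2 is None:
        cls = CLASS_UNASSIGNED
    elif tad1 == tad2:
        cls = CLASS_PRESERVING
    else:
        cls = CLASS_DISRUPTING
    return TadCall(sv.sv_id, sv.sample_id, cls, tad1, tad2)


def classify_all(svs: list[SvRecord], tads: pd.DataFrame) -> list[TadCall]:
    index = TadIndex(tads)
    return [classify_sv_tad(sv, index) for sv in svs]


def calls_frame(calls: list[TadCall]) -> pd.DataFrame:
    def fmt(t):
        return "" if t is None else f"{t[0]}:{t[1]}-{t[2]}"

    return pd.DataFrame(
        [
            {
                "sv_id": c.sv_id,
                "sample_id": c.sample_id,
                "tad_class": c.tad_class,
                "tad1": fmt(c.tad1),
                "tad2": fmt(c.tad2),
            }
            for c in calls
        ],
        columns=["sv_id", "sample_id", "tad_class", "tad1", "tad2"],
    )


def tad_enrichment(
    tad_calls: list[TadCall],
    assocs,
    overexpressed: set[tuple[str, str]],
) -> tuple[np.ndarray, float]:
    """2x2 chi-squared: TAD-disruption rate among gene-to-SV associations
    whose (gene, sample) pair is over-expressed versus the remaining
    associations.

    The unit of comparison is the association, not the raw SV: comparing
    against all SVs genome-wide is confounded, because translocations get
    two independent chances to land near a gene and are almost always
    disrupting, so the gene-linked subset over-samples them even with no
    mechanism at work.  Associations whose SV is unassigned (either
    breakpoint in a TAD gap) are excluded.  Returns (table, p).
    """
    cls = {c.sv_id: c.tad_class for c in tad_calls}
    table = np.zeros((2, 2))
    for a in assocs:
        tad_class = cls.get(a.sv_id, CLASS_UNASSIGNED)
        if tad_class == CLASS_UNASSIGNED:
            continue
        row = 0 if (a.gene_id, a.sample_id) in overexpressed else 1
        col = 0 if tad_class == CLASS_DISRUPTING else 1
        table[row, col] += 1
    _, p = chisq_2x2(table)
    return table, p
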