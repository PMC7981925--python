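"""Putative enhancer-translocation (enhancer hijacking) calls.

For a gene-to-SV association whose mate breakpoint is distal (another
chromosome or beyond the gene's 1 Mb flank), the rearrangement fuses the
mate's neighbourhood next to the gene.  Any enhancer near the mate is
therefore repositioned to an effective distance of

    d_new = d(bp_near_gene, TSS) + d(bp_mate, enhancer)

from the gene.  A call is an event when an enhancer exists within the
1 Mb scan of the mate, d_new is within the 500 kb hijack distance, and
d_new beats the closest native enhancer within 1 Mb upstream of the
unaltered gene.  Enhancer orientation is ignored (enhancers act
orientation-independently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import chisq_2x2
from .matrix import GeneSvAssociation
from .model import Config, GeneModel, SvRecord


@dataclass(frozen=True)
class EnhancerHijackCall:
    gene_id: str
    sample_id: str
    sv_id: str
    enhancer: tuple[str, int, int] | None
    d_bp2_to_enh: float  # bp; inf when no enhancer within the scan
    d_bp1_to_tss: int
    d_new: float  # modelled post-rearrangement gene-enhancer distance
    d_native: float  # closest native enhancer within 1 Mb upstream; inf if none
    is_event: bool


class _EnhancerIndex:
    """Per-chromosome sorted enhancer intervals for nearest-distance queries."""

    def __init__(self, enhancers: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in enhancers.groupby("chrom"):
            sub = sub.sort_values(["start", "end"])
            self._by_chrom[str(chrom)] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
            )

    def nearest(
        self, chrom: str, pos: int, max_dist: float = math.inf
    ) -> tuple[float, tuple[str, int, int] | None]:
        """(distance, interval) of the enhancer nearest ``pos`` within
        ``max_dist``; (inf, None) when there is none.  Distance is 0 when
        ``pos`` falls inside the enhancer, else bp to the nearest edge."""
        if chrom not in self._by_chrom:
            return math.inf, None
        starts, ends = self._by_chrom[chrom]
        d = np.maximum.reduce([starts - pos, pos - ends, np.zeros_like(starts)])
        j = int(np.argmin(d))
        if d[j] > max_dist:
            return math.inf, None
        return float(d[j]), (chrom, int(starts[j]), int(ends[j]))


def point_interval_distance(pos: int, start: int, end: int) -> int:
    """Gap in bp between a point and a half-open interval (0 when the point
    touches or falls inside it): ``start - pos`` to the left, ``pos - end``
    to the right."""
    return max(start - pos, pos - end, 0)


def native_enhancer_distance(
    gene: GeneModel, enhancers: pd.DataFrame, scan: int = 1_000_000
) -> float:
    """Distance from the strand-aware TSS to the closest enhancer overlapping
    the ``scan`` bp upstream window; 0 when an enhancer covers the TSS;
    inf when none is found."""
    tss = gene.tss
    if gene.strand == "+":
        wlo, whi = tss - scan, tss + 1
    else:
        wlo, whi = tss, tss + scan + 1
    best = math.inf
    sub = enhancers[enhancers["chrom"] == gene.chrom]
    for s, e in zip(sub["start"].to_numpy(int), sub["end"].to_numpy(int)):
        if s < whi and e > wlo:  # overlaps the upstream window
            best = min(best, point_interval_distance(tss, s, e))
    return best


def call_hijack(
    assoc: GeneSvAssociation,
    gene: GeneModel,
    sv: SvRecord,
    enhancers: pd.DataFrame | _EnhancerIndex,
    config: Config | None = None,
    d_native: float | None = None,
) -> EnhancerHijackCall | None:
    """Evaluate one association for an enhancer-translocation event.

    Returns None (no call) when the mate breakpoint is not distal.
    ``d_native`` may be supplied to avoid recomputing the native scan.
    """
    config = config or Config()
    if not assoc.mate_is_distal:
        return None
    index = (
        enhancers
        if isinstance(enhancers, _EnhancerIndex)
        else _EnhancerIndex(enhancers)
    )
    near = sv.bp1 if assoc.near_bp == 1 else sv.bp2
    mate = sv.mate_of(assoc.near_bp)
    d_enh, enh = index.nearest(mate.chrom, mate.pos, config.enhancer_scan_dist)
    d_tss = abs(near.pos - gene.tss)
    d_new = d_tss + d_enh
    if d_native is None:
        if isinstance(enhancers, _EnhancerIndex):
            raise ValueError("d_native required when passing a prebuilt index")
        d_native = native_enhancer_distance(gene, enhancers, config.enhancer_scan_dist)
    is_event = (
        math.isfinite(d_enh)
        and d_new <= config.hijack_max_dist
        and d_new < d_native
    )
    return EnhancerHijackCall(
        gene_id=gene.gene_id,
        sample_id=assoc.sample_id,
        sv_id=assoc.sv_id,
        enhancer=enh,
        d_bp2_to_enh=d_enh,
        d_bp1_to_tss=d_tss,
        d_new=d_new,
        d_native=d_native,
        is_event=is_event,
    )


def call_hijacks(
    assocs: list[GeneSvAssociation],
    genes: list[GeneModel],
    svs: list[SvRecord],
    enhancers: pd.DataFrame,
    config: Config | None = None,
) -> list[EnhancerHijackCall]:
    """Hijack calls for every distal-mate association in the list."""
    config = config or Config()
    index = _EnhancerIndex(enhancers)
    gene_by_id = {g.gene_id: g for g in genes}
    sv_by_id = {sv.sv_id: sv for sv in svs}
    native_cache: dict[str, float] = {}
    out = []
    for assoc in assocs:
        if not assoc.mate_is_distal:
            continue
        gene = gene_by_id[assoc.gene_id]
        if gene.gene_id not in native_cache:
            native_cache[gene.gene_id] = native_enhancer_distance(
                gene, enhancers, config.enhancer_scan_dist
            )
        call = call_hijack(
            assoc,
            gene,
            sv_by_id[assoc.sv_id],
            index,
            config,
            d_native=native_cache[gene.gene_id],
        )
        if call is not None:
            out.append(call)
    return out


def calls_frame(calls: list[EnhancerHijackCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "sample_id": c.sample_id,
                "sv_id": c.sv_id,
                "enhancer": "" if c.enhancer is None else
                f"{c.enhancer[0]}:{c.enhancer[1]}-{c.enhancer[2]}",
                "d_bp2_to_enh": c.d_bp2_to_enh,
                "d_bp1_to_tss": c.d_bp1_to_tss,
                "d_new": c.d_new,
                "d_native": c.d_native,
                "is_event": c.is_event,
            }
            for c in calls
        ],
        columns=[
            "gene_id", "sample_id", "sv_id", "enhancer", "d_bp2_to_enh",
            "d_bp1_to_tss", "d_new", "d_native", "is_event",
        ],
    )


def hijack_enrichment(
    calls: list[EnhancerHijackCall],
    overexpressed: set[tuple[str, str]],
) -> tuple[np.ndarray, float]:
    """2x2 chi-squared: event rate among calls whose (gene, sample) pair is
    over-expressed (gene significant and sample beyond the 0.4 SD rule)
    versus the remaining calls.  Returns (table, p)."""
    table = np.zeros((2, 2))
    for c in calls:
        row = 0 if (c.gene_id, c.sample_id) in overexpressed else 1
        col = 0 if c.is_event else 1
        table[row, col] += 1
    _, p = chisq_2x2(table)
    return table, p
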