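"""Gene-to-sample SV breakpoint matrices and gene-to-SV association lists.

The matrix has one row per gene and one column per cohort sample.  An
unweighted entry is 1 when at least one breakpoint of any SV of that sample
falls inside the chosen region window of the gene, 0 otherwise.  For the
1 Mb flank window a "distance metric" variant is available in which each
breakpoint contributes a weight that decays linearly from 1 (inside the
gene body) to 0 (at the 1 Mb edge); the entry is the per-sample maximum
over breakpoints, so near breakpoints dominate while distant ones within
1 Mb retain some influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .model import Breakpoint, Config, GeneModel, RegionWindow, SvRecord


@dataclass
class BreakpointMatrix:
    """Gene x sample breakpoint pattern in [0, 1]."""

    values: pd.DataFrame
    window: RegionWindow
    weighted: bool

    def __post_init__(self) -> None:
        if self.weighted and self.window is not RegionWindow.FLANK_1MB:
            raise ValueError("distance weighting applies only to the 1 Mb flank window")


@dataclass(frozen=True)
class GeneSvAssociation:
    """One (gene, sample) link to the single breakpoint closest to the TSS."""

    gene_id: str
    sample_id: str
    sv_id: str
    near_bp: int  # mate_index of the breakpoint inside the gene's window
    distance_to_gene: int  # bp to the gene body edge; 0 inside the body
    mate_is_distal: bool  # mate on another chromosome or outside the 1 Mb flank


def window_interval(
    gene: GeneModel, window: RegionWindow, size: int
) -> tuple[str, int, int]:
    """Half-open genomic interval of a region window, clipped at 0.

    Upstream/downstream are strand-aware; the flank window spans the body
    plus ``size`` on both sides.
    """
    if window is RegionWindow.GENE_BODY:
        lo, hi = gene.start, gene.end
    elif window is RegionWindow.FLANK_1MB:
        lo, hi = gene.start - size, gene.end + size
    elif window is RegionWindow.UPSTREAM_100KB:
        if size <= 0:
            raise ValueError("window size must be positive")
        if gene.strand == "+":
            lo, hi = gene.start - size, gene.start
        else:
            lo, hi = gene.end, gene.end + size
    elif window is RegionWindow.DOWNSTREAM_100KB:
        if gene.strand == "+":
            lo, hi = gene.end, gene.end + size
        else:
            lo, hi = gene.start - size, gene.start
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown window {window}")
    return gene.chrom, max(lo, 0), max(hi, 0)


def distance_to_gene(pos: int, gene: GeneModel) -> int:
    """Distance from a breakpoint to the gene: 0 inside the body, else the
    smaller of the distances to the two body coordinates."""
    if gene.start <= pos < gene.end:
        return 0
    return min(abs(pos - gene.start), abs(pos - gene.end))


def breakpoint_weight(distance: int, window_size: int) -> float:
    """Linear distance decay: 1 at the gene, 0 at the window edge."""
    if not 0 <= distance <= window_size:
        raise ValueError(
            f"distance {distance} outside [0, {window_size}]; callers must "
            "pre-filter to the window"
        )
    return 1.0 - distance / window_size


def _window_trees(
    genes: list[GeneModel], window: RegionWindow, size: int
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        chrom, lo, hi = window_interval(gene, window, size)
        if lo >= hi:  # fully clipped away
            continue
        trees.setdefault(chrom, IntervalTree()).addi(lo, hi, gene)
    return trees


def _iter_breakpoints(svs: list[SvRecord]) -> list[Breakpoint]:
    return [bp for sv in svs for bp in sv.breakpoints]


def _cohort(svs: list[SvRecord], samples: list[str] | None) -> list[str]:
    if samples is not None:
        return list(samples)
    return sorted({sv.sample_id for sv in svs})


def build_matrix(
    genes: list[GeneModel],
    svs: list[SvRecord],
    window: RegionWindow,
    config: Config | None = None,
    samples: list[str] | None = None,
    weighted: bool | None = None,
    sv_type: str | None = None,
) -> BreakpointMatrix:
    """Build the gene-to-sample breakpoint matrix for one region window.

    Both breakpoints of every SV are tested independently.  ``samples``
    fixes the cohort (samples with zero SVs keep all-zero columns); when
    omitted the cohort is the set of samples present in the SV table.
    ``sv_type`` filters the SV table to one type before counting.
    """
    config = config or Config()
    if weighted is None:
        weighted = config.use_distance_metric and window is RegionWindow.FLANK_1MB
    if not genes:
        raise ValueError("empty gene set")
    cohort = _cohort(svs, samples)
    if not cohort:
        raise ValueError("empty sample cohort")
    if sv_type is not None:
        svs = [sv for sv in svs if sv.sv_type == sv_type]
    size = config.window_size(window)
    trees = _window_trees(genes, window, size)
    values = pd.DataFrame(
        0.0, index=[g.gene_id for g in genes], columns=cohort
    )
    col_ok = set(cohort)
    for bp in _iter_breakpoints(svs):
        if bp.sample_id not in col_ok:
            continue
        tree = trees.get(bp.chrom)
        if tree is None:
            continue
        for iv in tree.at(bp.pos):
            gene: GeneModel = iv.data
            if weighted:
                w = breakpoint_weight(distance_to_gene(bp.pos, gene), size)
                if w > values.at[gene.gene_id, bp.sample_id]:
                    values.at[gene.gene_id, bp.sample_id] = w
            else:
                values.at[gene.gene_id, bp.sample_id] = 1.0
    return BreakpointMatrix(values=values, window=window, weighted=bool(weighted))


def gene_sv_associations(
    genes: list[GeneModel],
    svs: list[SvRecord],
    window: RegionWindow,
    config: Config | None = None,
    sv_type: str | None = None,
) -> list[GeneSvAssociation]:
    """One association per (gene, sample) with any in-window breakpoint.

    When several breakpoints fall in the window the one closest to the
    gene start (strand-aware TSS) is reported; ties break to the lower
    genomic coordinate, then the lexicographically smaller sv_id.  The
    mate is flagged distal when it lies on another chromosome or outside
    the gene's 1 Mb flank interval.
    """
    config = config or Config()
    if not genes:
        raise ValueError("empty gene set")
    if sv_type is not None:
        svs = [sv for sv in svs if sv.sv_type == sv_type]
    size = config.window_size(window)
    flank = config.window_size(RegionWindow.FLANK_1MB)
    trees = _window_trees(genes, window, size)
    sv_by_id = {sv.sv_id: sv for sv in svs}
    # best[(gene_id, sample_id)] = (tss_dist, pos, sv_id, mate_index)
    best: dict[tuple[str, str], tuple[int, int, str, int]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for bp in _iter_breakpoints(svs):
        tree = trees.get(bp.chrom)
        if tree is None:
            continue
        for iv in tree.at(bp.pos):
            gene: GeneModel = iv.data
            key = (gene.gene_id, bp.sample_id)
            cand = (abs(bp.pos - gene.tss), bp.pos, bp.sv_id, bp.mate_index)
            if key not in best or cand < best[key]:
                best[key] = cand
    out: list[GeneSvAssociation] = []
    for (gene_id, sample_id), (_, pos, sv_id, mate_index) in sorted(best.items()):
        gene = gene_by_id[gene_id]
        mate = sv_by_id[sv_id].mate_of(mate_index)
        _, flo, fhi = window_interval(gene, RegionWindow.FLANK_1MB, flank)
        mate_is_distal = mate.chrom != gene.chrom or not flo <= mate.pos < fhi
        out.append(
            GeneSvAssociation(
                gene_id=gene_id,
                sample_id=sample_id,
                sv_id=sv_id,
                near_bp=mate_index,
                distance_to_gene=distance_to_gene(pos, gene),
                mate_is_distal=mate_is_distal,
            )
        )
    return out


def associations_frame(assocs: list[GeneSvAssociation]) -> pd.DataFrame:
    """Associations as a writable table."""
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "sample_id": a.sample_id,
                "sv_id": a.sv_id,
                "near_bp": a.near_bp,
                "distance_to_gene": a.distance_to_gene,
                "mate_is_distal": a.mate_is_distal,
            }
            for a in assocs
        ],
        columns=[
            "gene_id",
            "sample_id",
            "sv_id",
            "near_bp",
            "distance_to_gene",
            "mate_is_distal",
        ],
    )
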