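"""Core domain types and coordinate conventions.

All coordinates inside the package are 0-based half-open (BED convention).
SV caller position columns are assumed 1-based and are converted once, at
read time (see :mod:`svgex.io`); nothing downstream converts again.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class RegionWindow(enum.Enum):
    """Genomic region, relative to a gene, in which breakpoints are counted.

    ``UPSTREAM_100KB`` / ``DOWNSTREAM_100KB`` are strand-aware; ``FLANK_1MB``
    spans the gene body plus the flanking distance on both sides and is the
    only window eligible for distance weighting.
    """

    UPSTREAM_100KB = "up100k"
    DOWNSTREAM_100KB = "down100k"
    GENE_BODY = "body"
    FLANK_1MB = "flank1mb"

    @classmethod
    def from_name(cls, name: str) -> "RegionWindow":
        for w in cls:
            if name in (w.name, w.value):
                return w
        raise ValueError(f"unknown region window: {name!r}")


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene coordinates; the anchor for every region window."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end "
                f"(got {self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand-aware; 0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Breakpoint:
    """One side of an SV junction; every SV has exactly two (mates)."""

    chrom: str
    pos: int
    sv_id: str
    mate_index: int  # 1 or 2
    sample_id: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"breakpoint {self.sv_id}: negative position")
        if self.mate_index not in (1, 2):
            raise ValueError(f"breakpoint {self.sv_id}: mate_index must be 1 or 2")


@dataclass(frozen=True)
class SvRecord:
    """A two-breakpoint somatic rearrangement in one sample."""

    sv_id: str
    sample_id: str
    bp1: Breakpoint
    bp2: Breakpoint
    sv_type: str | None = None

    def __post_init__(self) -> None:
        for bp in (self.bp1, self.bp2):
            if bp.sv_id != self.sv_id or bp.sample_id != self.sample_id:
                raise ValueError(f"SV {self.sv_id}: breakpoint ids do not match record")

    @property
    def breakpoints(self) -> tuple[Breakpoint, Breakpoint]:
        return (self.bp1, self.bp2)

    def mate_of(self, mate_index: int) -> Breakpoint:
        """The other breakpoint, given the mate_index of one of them."""
        return self.bp2 if mate_index == 1 else self.bp1


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    cancer_type: str


@dataclass
class Config:
    """Pipeline constants.

    Distances are in bp.  ``overexpr_sd_threshold`` is the number of
    cross-sample standard deviations above the gene's cross-sample median
    beyond which a sample counts as over-expressing the gene.
    """

    window_sizes: dict = field(
        default_factory=lambda: {
            RegionWindow.UPSTREAM_100KB: 100_000,
            RegionWindow.DOWNSTREAM_100KB: 100_000,
            RegionWindow.GENE_BODY: 0,
            RegionWindow.FLANK_1MB: 1_000_000,
        }
    )
    use_distance_metric: bool = False
    overexpr_sd_threshold: float = 0.4
    hijack_max_dist: int = 500_000
    enhancer_scan_dist: int = 1_000_000
    fusion_p_threshold: float = 0.01
    fdr_threshold: float = 0.10
    min_altered_samples: int = 1

    def __post_init__(self) -> None:
        for w, s in self.window_sizes.items():
            if w is not RegionWindow.GENE_BODY and s <= 0:
                raise ValueError(f"window size for {w} must be positive")
        if not 0 < self.fusion_p_threshold < 1:
            raise ValueError("fusion_p_threshold must be in (0,1)")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0,1)")
        if self.hijack_max_dist <= 0 or self.enhancer_scan_dist <= 0:
            raise ValueError("distances must be positive")

    def window_size(self, window: RegionWindow) -> int:
        return self.window_sizes[window]
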