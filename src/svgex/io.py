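"""Readers and writers for every table the pipeline touches.

Formats: TSV for the SV table, gene table, matrices and sample annotation
(header row, gene ids in the first column for matrices); BED (0-based
half-open) for enhancers and TAD intervals.  All readers are
gzip-transparent via pandas.

Coordinate conversion happens here and only here: SV caller positions are
read as 1-based and stored 0-based; BED files are already 0-based half-open.
Chromosome names are normalised to the ``chr``-prefixed dialect
(``MT``/``M`` unified to ``chrM``) so that SV calls, gene tables and BEDs
from different sources agree.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .model import Breakpoint, GeneModel, SampleAnnotation, SvRecord

logger = logging.getLogger(__name__)

DEFAULT_SV_COLUMNS = {
    "sample": "sample",
    "chrom1": "chrom1",
    "pos1": "pos1",
    "chrom2": "chrom2",
    "pos2": "pos2",
}


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the ``chr``-prefixed dialect."""
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in ("MT", "M", "mt", "m"):
        name = "M"
    return f"chr{name}"


def read_sv_table(
    path: str | Path,
    column_mapping: dict[str, str] | None = None,
    sep: str = "\t",
) -> list[SvRecord]:
    """Read a somatic SV table (one row per SV, two breakpoints).

    ``column_mapping`` maps the required logical names (``sample``,
    ``chrom1``, ``pos1``, ``chrom2``, ``pos2``; optionally ``sv_id``,
    ``sv_type``) to the file's column names, so the standard output of any
    SV caller can be adapted.  Positions are 1-based in the file and stored
    0-based.  When no ``sv_id`` column is mapped, ids are assigned from row
    order, so duplicated rows stay distinct records.

    SVs whose two breakpoints have identical coordinates carry no positional
    information and are dropped with a warning.
    """
    mapping = dict(DEFAULT_SV_COLUMNS)
    if column_mapping:
        mapping.update(column_mapping)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for logical in ("sample", "chrom1", "pos1", "chrom2", "pos2"):
        col = mapping[logical]
        if col not in df.columns:
            raise ValueError(
                f"SV table {path} is missing required column {col!r} "
                f"(mapped from {logical!r})"
            )
    records: list[SvRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        sample = str(row[mapping["sample"]])
        pos = {}
        for key in ("pos1", "pos2"):
            raw = row[mapping[key]]
            try:
                pos[key] = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"SV table {path}, data row {i + 1}: non-integer "
                    f"position {raw!r} in column {mapping[key]!r}"
                ) from None
        chrom1 = normalize_chrom(row[mapping["chrom1"]])
        chrom2 = normalize_chrom(row[mapping["chrom2"]])
        if chrom1 == chrom2 and pos["pos1"] == pos["pos2"]:
            n_dropped += 1
            continue
        sv_id_col = mapping.get("sv_id")
        sv_id = (
            str(row[sv_id_col])
            if sv_id_col and sv_id_col in row and pd.notna(row[sv_id_col])
            else f"sv{i + 1:06d}"
        )
        sv_type_col = mapping.get("sv_type")
        sv_type = (
            str(row[sv_type_col])
            if sv_type_col and sv_type_col in row and pd.notna(row[sv_type_col])
            else None
        )
        bp1 = Breakpoint(chrom1, pos["pos1"] - 1, sv_id, 1, sample)
        bp2 = Breakpoint(chrom2, pos["pos2"] - 1, sv_id, 2, sample)
        records.append(SvRecord(sv_id, sample, bp1, bp2, sv_type))
    if n_dropped:
        logger.warning(
            "dropped %d degenerate SV record(s) with both breakpoints at "
            "identical coordinates",
            n_dropped,
        )
    return records


def write_sv_table(svs: list[SvRecord], path: str | Path) -> None:
    """Write SVs back in reader format (positions re-emitted 1-based)."""
    rows = [
        {
            "sample": sv.sample_id,
            "chrom1": sv.bp1.chrom,
            "pos1": sv.bp1.pos + 1,
            "chrom2": sv.bp2.chrom,
            "pos2": sv.bp2.pos + 1,
            "sv_id": sv.sv_id,
            "sv_type": sv.sv_type if sv.sv_type is not None else "",
        }
        for sv in svs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene coordinate table: gene_id, chrom, start, end, strand.

    Coordinates are 0-based half-open (BED-like).  gene_id must be unique.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} is missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene ids in {path}: {list(dups)[:5]}")
    return [
        GeneModel(
            str(r.gene_id),
            normalize_chrom(r.chrom),
            int(r.start),
            int(r.end),
            str(r.strand),
        )
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample numeric matrix (TSV, gene ids in column 1).

    Duplicate gene ids or sample ids are rejected; any non-numeric cell is a
    hard error naming its coordinates.
    """
    # pandas de-duplicates repeated header names silently; check the raw line
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dups[:5]}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix {path}: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate gene ids in {path}: {list(dups)[:5]}")
    for col in df.columns:
        if df[col].dtype == object:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell in {path} at gene {gene!r}, sample {col!r}"
                )
            df[col] = converted
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "gene_id") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED into a (chrom, start, end[, name]) frame.

    Intervals are 0-based half-open per the BED standard; ``start >= end``
    is a hard error with the offending line number.
    """
    # fixed BED12 name set so rows may carry different numbers of fields
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=range(12), engine="python"
    )
    df = df.dropna(axis=1, how="all")
    if df.shape[1] < 3 or df.iloc[:, :3].isna().any().any():
        raise ValueError(f"BED file {path} needs at least 3 columns on every line")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].map(normalize_chrom)
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    if df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3].astype(str)
    bad = out["start"] >= out["end"]
    if bad.any():
        line = int(bad.to_numpy().argmax()) + 1
        raise ValueError(f"BED file {path}, line {line}: start >= end")
    return out


def write_bed_intervals(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_sample_annotation(path: str | Path) -> list[SampleAnnotation]:
    """Read sample_id / cancer_type pairs; sample_id must be unique."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "cancer_type" not in df.columns:
        raise ValueError(f"{path} must have sample_id and cancer_type columns")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    return [
        SampleAnnotation(str(r.sample_id), str(r.cancer_type))
        for r in df.itertuples(index=False)
    ]


def write_sample_annotation(annot: list[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": a.sample_id, "cancer_type": a.cancer_type} for a in annot]
    ).to_csv(path, sep="\t", index=False)
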