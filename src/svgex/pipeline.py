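"""End-to-end orchestration: matrix -> associate -> hijack -> tad -> fusions.

Driven by a YAML config naming the input files; stages whose inputs are
absent are skipped with a log line.  Every run writes a manifest with the
tool version, the config snapshot and SHA-256 digests of the inputs, so a
result set is traceable to exactly the files that produced it.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as svio
from .association import (
    MODEL_TYPE_ONLY,
    MODEL_TYPE_PLUS_CNA,
    overexpression_flags,
    run_association_screen,
)
from .fusions import annotate_high_expression, annotate_sv_support, support_summary
from .hijack import call_hijacks, calls_frame as hijack_frame, hijack_enrichment
from .matrix import associations_frame, build_matrix, gene_sv_associations
from .model import Config, RegionWindow
from .tads import calls_frame as tad_frame, classify_all, tad_enrichment

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError(f"{config_path}: expected a mapping with an 'inputs' section")
    return cfg


def overexpressed_pairs(
    screen: pd.DataFrame,
    expr: pd.DataFrame,
    config: Config,
    window: RegionWindow = RegionWindow.FLANK_1MB,
) -> set[tuple[str, str]]:
    """(gene, sample) pairs where the gene is screen-significant (CNA-corrected
    family when present) and the sample exceeds the 0.4 SD over-expression
    rule for that gene."""
    model = (
        MODEL_TYPE_PLUS_CNA
        if (screen["model"] == MODEL_TYPE_PLUS_CNA).any()
        else MODEL_TYPE_ONLY
    )
    sig = set(
        screen.loc[
            (screen["window"] == window.value)
            & (screen["model"] == model)
            & screen["significant"],
            "gene_id",
        ]
    )
    over = overexpression_flags(expr, config.overexpr_sd_threshold)
    pairs = set()
    for g in sig & set(over.index):
        row = over.loc[g]
        for s in row.index[row.fillna(False)]:
            pairs.add((g, s))
    return pairs


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Run every stage whose inputs exist; returns a summary dict."""
    cfg = load_config(config_path)
    inputs = cfg.get("inputs", {})
    params = cfg.get("params", {}) or {}
    outdir = Path(outdir or cfg.get("outdir", "svgex_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    config = Config(
        use_distance_metric=bool(params.get("distance_weight", True)),
        fdr_threshold=float(params.get("fdr", 0.10)),
        min_altered_samples=int(params.get("min_altered_samples", 1)),
        overexpr_sd_threshold=float(params.get("overexpr_sd", 0.4)),
        hijack_max_dist=int(params.get("hijack_max_dist", 500_000)),
        enhancer_scan_dist=int(params.get("enhancer_scan_dist", 1_000_000)),
        fusion_p_threshold=float(params.get("fusion_p", 0.01)),
    )

    def path_of(key: str) -> Path | None:
        p = inputs.get(key)
        if p is None:
            return None
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"input '{key}' not found: {p}")
        return p

    for key in ("svs", "genes", "expression", "samples"):
        if inputs.get(key) is None:
            raise ValueError(f"config must name the '{key}' input")

    svs = svio.read_sv_table(path_of("svs"))
    genes = svio.read_gene_table(path_of("genes"))
    expr = svio.read_matrix(path_of("expression"))
    annot = svio.read_sample_annotation(path_of("samples"))
    cna = svio.read_matrix(path_of("cna")) if inputs.get("cna") else None
    samples = [a.sample_id for a in annot]

    summary: dict = {"stages": {}}

    # --- matrix stage -----------------------------------------------------
    window_names = params.get("windows", ["flank1mb", "body"])
    matrices = []
    for name in window_names:
        window = RegionWindow.from_name(name)
        weighted = config.use_distance_metric and window is RegionWindow.FLANK_1MB
        bpm = build_matrix(genes, svs, window, config, samples=samples, weighted=weighted)
        suffix = f"{window.value}{'_weighted' if weighted else ''}"
        svio.write_matrix(bpm.values, outdir / f"matrix_{suffix}.tsv")
        matrices.append(bpm)
    assocs = gene_sv_associations(genes, svs, RegionWindow.FLANK_1MB, config)
    associations_frame(assocs).to_csv(outdir / "associations.tsv", sep="\t", index=False)
    summary["stages"]["matrix"] = {
        "windows": window_names,
        "n_associations": len(assocs),
    }

    # --- association screen ----------------------------------------------
    screen = run_association_screen(
        expr, matrices, annot, cna, config, n_jobs=int(params.get("threads", 1))
    )
    screen.to_csv(outdir / "associations_screen.tsv", sep="\t", index=False)
    summary["stages"]["associate"] = {
        "n_significant": int(screen["significant"].sum()),
    }
    over_pairs = overexpressed_pairs(screen, expr, config)

    # --- enhancer hijack --------------------------------------------------
    if inputs.get("enhancers"):
        enhancers = svio.read_bed_intervals(path_of("enhancers"))
        calls = call_hijacks(assocs, genes, svs, enhancers, config)
        hijack_frame(calls).to_csv(outdir / "hijack_calls.tsv", sep="\t", index=False)
        table, p = hijack_enrichment(calls, over_pairs)
        pd.DataFrame(
            table,
            index=["overexpressed", "other"],
            columns=["event", "no_event"],
        ).to_csv(outdir / "hijack_enrichment.tsv", sep="\t")
        summary["stages"]["hijack"] = {
            "n_calls": len(calls),
            "n_events": int(sum(c.is_event for c in calls)),
            "enrichment_p": p,
        }
    else:
        logger.info("no enhancer BED given; hijack stage skipped")
        summary["stages"]["hijack"] = "skipped"

    # --- TAD disruption ---------------------------------------------------
    if inputs.get("tads"):
        tads = svio.read_bed_intervals(path_of("tads"))
        tad_calls = classify_all(svs, tads)
        tad_frame(tad_calls).to_csv(outdir / "tad_calls.tsv", sep="\t", index=False)
        table, p = tad_enrichment(tad_calls, assocs, over_pairs)
        pd.DataFrame(
            table,
            index=["overexpressed", "other"],
            columns=["disrupting", "preserving"],
        ).to_csv(outdir / "tad_enrichment.tsv", sep="\t")
        summary["stages"]["tad"] = {
            "n_disrupting": sum(c.tad_class == "disrupting" for c in tad_calls),
            "n_preserving": sum(c.tad_class == "preserving" for c in tad_calls),
            "enrichment_p": p,
        }
    else:
        logger.info("no TAD BED given; tad stage skipped")
        summary["stages"]["tad"] = "skipped"

    # --- fusion support ---------------------------------------------------
    if inputs.get("fusions"):
        fusions = pd.read_csv(path_of("fusions"), sep="\t")
        fusions = annotate_sv_support(fusions, genes, svs)
        fusions = annotate_high_expression(fusions, expr, screen, config)
        fusions.to_csv(outdir / "fusion_support.tsv", sep="\t", index=False)
        summary["stages"]["fusions"] = support_summary(fusions)
    else:
        logger.info("no fusion candidate table given; fusion stage skipped")
        summary["stages"]["fusions"] = "skipped"

    manifest = {
        "tool": "svgex",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": cfg,
        "input_digests": {
            key: _sha256(Path(p)) for key, p in inputs.items() if p and Path(p).exists()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    summary["outdir"] = str(outdir)
    return summary
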