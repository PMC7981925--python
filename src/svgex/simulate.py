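"""Seed-controlled synthetic cancer cohorts for end-to-end testing.

The generator emulates the statistical structure the breakpoint-expression
screen assumes: a cohort of samples from several cancer types, somatic SVs
(a mix of short intrachromosomal events and translocations), log-scale
expression with Gaussian noise, per-gene copy number, enhancer and TAD
annotations, and a truth table of planted effects.

Expression for a planted effect gene is shifted by ``effect_size_sd``
(in residual-SD units) in every sample carrying a breakpoint within the
gene's 1 Mb flank window — the generative model matches the screen's
regression, so recovery tests measure the screen, not model mismatch.
CNA confounding is planted as focal amplification: a disjoint gene set
whose altered samples gain copy number (which couples into expression)
with no direct SV effect, so the CNA-corrected model should drop them.

Mechanism presets shape the planted SVs:

* ``hijack`` — planted SVs are translocations whose mate lands next to an
  enhancer while the gene's own upstream megabase is kept enhancer-free,
  giving a callable enhancer-translocation geometry.
* ``tad`` — planted SVs span a TAD boundary (both breakpoints inside
  different TADs on the same chromosome).
* mechanism-free planted SVs reuse the background SV geometry exactly
  (breakpoint uniform in the flank window, same mate mix), so mechanism
  enrichment statistics stay null-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as svio
from .matrix import build_matrix
from .model import Breakpoint, Config, GeneModel, RegionWindow, SampleAnnotation, SvRecord


@dataclass
class SimConfig:
    """Synthetic-cohort parameters.

    ``effect_size_sd`` is the expression shift per altered sample in units
    of the residual (noise) SD.  ``altered_frac`` sets how many cohort
    samples receive a planted SV per effect gene.  Fractions are in [0,1].
    """

    n_genes: int = 1000
    n_samples: int = 200
    n_cancer_types: int = 4
    n_svs: int = 1600  # background SVs across the cohort
    effect_size_sd: float = 2.0
    frac_genes_with_effect: float = 0.05
    altered_frac: float = 0.05
    frac_genes_cna_confounded: float = 0.05
    cna_confounding_strength: float = 3.0  # focal-amplification copy shift
    cna_dosage_coupling: float = 0.5  # expression SD per copy-number unit
    cancer_type_sd: float = 0.3
    frac_hijack_mechanism: float = 0.0
    frac_tad_mechanism: float = 0.0
    n_fusion_pairs: int = 0
    n_chroms: int = 4
    chrom_length: int = 60_000_000
    enhancers_per_mb: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_genes_with_effect",
            "altered_frac",
            "frac_genes_cna_confounded",
            "frac_hijack_mechanism",
            "frac_tad_mechanism",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for name in ("n_genes", "n_samples", "n_cancer_types", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chrom_length < 5_000_000:
            raise ValueError("chromosomes must be at least 5 Mb for gene placement")
        genome = self.n_chroms * self.chrom_length
        if self.n_svs > genome // 1000:
            raise ValueError("too many SVs for the genome size")


@dataclass
class Cohort:
    """Everything the pipeline consumes, plus the planted truth."""

    genes: list[GeneModel]
    svs: list[SvRecord]
    expr: pd.DataFrame
    cna: pd.DataFrame
    sample_annotation: list[SampleAnnotation]
    enhancers: pd.DataFrame
    tads: pd.DataFrame
    fusions: pd.DataFrame | None
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)

    @property
    def samples(self) -> list[str]:
        return [a.sample_id for a in self.sample_annotation]


def _make_tads(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(0, 50_000))
        while pos < cfg.chrom_length - 1_500_000:
            length = int(rng.integers(600_000, 1_200_000))
            rows.append({"chrom": chrom, "start": pos, "end": pos + length})
            pos += length + int(rng.integers(20_000, 80_000))
    return pd.DataFrame(rows)


def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    margin = 1_500_000
    for i in range(cfg.n_genes):
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        length = int(rng.integers(20_000, 150_000))
        start = int(rng.integers(margin, cfg.chrom_length - margin - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i + 1:05d}", chrom, start, start + length, strand))
    return genes


def _make_enhancers(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        n = int(cfg.chrom_length / 1e6 * cfg.enhancers_per_mb)
        starts = np.sort(rng.integers(0, cfg.chrom_length - 2000, size=n))
        for s in starts:
            rows.append({"chrom": chrom, "start": int(s), "end": int(s) + 2000})
    return pd.DataFrame(rows)


def _random_mate(
    cfg: SimConfig, rng: np.random.Generator, chrom: str, pos: int
) -> tuple[str, int]:
    """Background mate geometry: 70% short intrachromosomal events
    (deletion/duplication/inversion-like, 50-500 kb), 30% translocations —
    the approximate spectrum of somatic SV calls."""
    if rng.random() < 0.7:
        size = int(rng.integers(50_000, 500_000))
        direction = 1 if rng.random() < 0.5 else -1
        mate_pos = min(max(pos + direction * size, 0), cfg.chrom_length - 1)
        return chrom, mate_pos
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms) if f"chr{i + 1}" != chrom]
    mate_chrom = chroms[int(rng.integers(len(chroms)))] if chroms else chrom
    return mate_chrom, int(rng.integers(0, cfg.chrom_length))


def _sv(sv_id: str, sample: str, c1: str, p1: int, c2: str, p2: int,
        sv_type: str | None = None) -> SvRecord:
    return SvRecord(
        sv_id,
        sample,
        Breakpoint(c1, p1, sv_id, 1, sample),
        Breakpoint(c2, p2, sv_id, 2, sample),
        sv_type,
    )


def _tad_of(tads: pd.DataFrame, chrom: str, pos: int):
    sub = tads[(tads["chrom"] == chrom) & (tads["start"] <= pos) & (pos < tads["end"])]
    return None if sub.empty else (sub.iloc[0]["start"], sub.iloc[0]["end"])


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full synthetic cohort; byte-identical per seed."""
    rng = np.random.default_rng(cfg.seed)
    tads = _make_tads(cfg, rng)
    genes = _make_genes(cfg, rng)
    enhancers = _make_enhancers(cfg, rng)

    samples = [f"s{i + 1:04d}" for i in range(cfg.n_samples)]
    types = [f"ct{(i % cfg.n_cancer_types) + 1}" for i in range(cfg.n_samples)]
    annot = [SampleAnnotation(s, t) for s, t in zip(samples, types)]

    # planted gene sets
    n_eff = round(cfg.frac_genes_with_effect * cfg.n_genes)
    perm = rng.permutation(cfg.n_genes)
    effect_idx = perm[:n_eff]
    n_conf = round(cfg.frac_genes_cna_confounded * cfg.n_genes)
    conf_idx = perm[n_eff:n_eff + n_conf]
    n_hijack = round(cfg.frac_hijack_mechanism * n_eff)
    n_tad = round(cfg.frac_tad_mechanism * n_eff)
    mechanism = {}
    for rank, gi in enumerate(effect_idx):
        if rank < n_hijack:
            mechanism[gi] = "hijack"
        elif rank < n_hijack + n_tad:
            mechanism[gi] = "tad"
        else:
            mechanism[gi] = "none"

    svs: list[SvRecord] = []
    sv_counter = 0

    def next_id() -> str:
        nonlocal sv_counter
        sv_counter += 1
        return f"sv{sv_counter:06d}"

    # background SVs
    for _ in range(cfg.n_svs):
        sample = samples[int(rng.integers(cfg.n_samples))]
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        pos = int(rng.integers(0, cfg.chrom_length))
        mc, mp = _random_mate(cfg, rng, chrom, pos)
        svs.append(_sv(next_id(), sample, chrom, pos, mc, mp))

    # planted effect SVs
    flank = Config().window_size(RegionWindow.FLANK_1MB)
    k_alt = max(2, round(cfg.altered_frac * cfg.n_samples))
    planted_enhancers: list[dict] = []
    cleared_regions: list[tuple[str, int, int]] = []
    planted_samples: dict[int, np.ndarray] = {}
    for gi in effect_idx:
        gene = genes[gi]
        mech = mechanism[gi]
        chosen = rng.choice(cfg.n_samples, size=min(k_alt, cfg.n_samples), replace=False)
        planted_samples[gi] = chosen
        if mech == "hijack":
            cleared_regions.append(
                (gene.chrom, gene.tss - flank - 100_000, gene.tss + flank + 100_000)
            )
        for si in chosen:
            sample = samples[int(si)]
            if mech == "hijack":
                d = int(rng.integers(10_000, 300_000))
                pos = gene.tss - d if gene.strand == "+" else gene.tss + d
                pos = min(max(pos, 0), cfg.chrom_length - 1)
                others = [f"chr{i + 1}" for i in range(cfg.n_chroms)
                          if f"chr{i + 1}" != gene.chrom]
                mc = others[int(rng.integers(len(others)))] if others else gene.chrom
                mp = int(rng.integers(200_000, cfg.chrom_length - 200_000))
                e_start = mp + int(rng.integers(5_000, 100_000))
                planted_enhancers.append(
                    {"chrom": mc, "start": e_start, "end": e_start + 2000}
                )
                svs.append(_sv(next_id(), sample, gene.chrom, pos, mc, mp))
            elif mech == "tad":
                lo = max(gene.start - flank, 0)
                hi = min(gene.end + flank, cfg.chrom_length)
                pos = None
                for _ in range(100):
                    cand = int(rng.integers(lo, hi))
                    if _tad_of(tads, gene.chrom, cand) is not None:
                        pos = cand
                        break
                if pos is None:
                    pos = int(rng.integers(lo, hi))
                own = _tad_of(tads, gene.chrom, pos)
                chrom_tads = tads[tads["chrom"] == gene.chrom]
                other = chrom_tads[chrom_tads["start"] != (own[0] if own else -1)]
                row = other.iloc[int(rng.integers(len(other)))]
                mp = int(rng.integers(row["start"], row["end"]))
                svs.append(_sv(next_id(), sample, gene.chrom, pos, gene.chrom, mp))
            else:
                lo = max(gene.start - flank, 0)
                hi = min(gene.end + flank, cfg.chrom_length)
                pos = int(rng.integers(lo, hi))
                mc, mp = _random_mate(cfg, rng, gene.chrom, pos)
                svs.append(_sv(next_id(), sample, gene.chrom, pos, mc, mp))

    # hijack geometry requires an enhancer-free native neighbourhood
    for chrom, lo, hi in cleared_regions:
        keep = ~(
            (enhancers["chrom"] == chrom)
            & (enhancers["end"] > lo)
            & (enhancers["start"] < hi)
        )
        enhancers = enhancers[keep]
    if planted_enhancers:
        enhancers = pd.concat(
            [enhancers, pd.DataFrame(planted_enhancers)], ignore_index=True
        )
    enhancers = enhancers.sort_values(["chrom", "start"]).reset_index(drop=True)

    # fusion candidates: planted supported pairs plus unsupported decoys
    fusions = None
    if cfg.n_fusion_pairs > 0:
        rows = []
        for fi in range(cfg.n_fusion_pairs):
            ga, gb = (genes[i] for i in rng.choice(cfg.n_genes, size=2, replace=False))
            sample = samples[int(rng.integers(cfg.n_samples))]
            if fi % 2 == 0:  # SV-supported: breakpoints inside both bodies
                pa = int(rng.integers(ga.start, ga.end))
                pb = int(rng.integers(gb.start, gb.end))
                svs.append(_sv(next_id(), sample, ga.chrom, pa, gb.chrom, pb))
            rows.append({"gene5": ga.gene_id, "gene3": gb.gene_id, "sample": sample})
        fusions = pd.DataFrame(rows)

    # breakpoint pattern drives the planted expression / CNA shifts.  For
    # mechanism-free effect genes any flank breakpoint deregulates the gene
    # (the model the screen assumes); for hijack/tad genes only the planted
    # mechanism SVs do, so over-expression traces the mechanism geometry.
    bpm = build_matrix(genes, svs, RegionWindow.FLANK_1MB, samples=samples)
    B = (bpm.values.to_numpy() > 0).astype(float)
    E = B.copy()
    for gi, chosen in planted_samples.items():
        if mechanism[gi] != "none":
            row = np.zeros(cfg.n_samples)
            row[np.asarray(chosen, int)] = 1.0
            E[gi] = row

    gene_ids = [g.gene_id for g in genes]
    type_codes = np.array([int(t[2:]) - 1 for t in types])
    ct_means = rng.normal(0.0, cfg.cancer_type_sd, size=(cfg.n_genes, cfg.n_cancer_types))
    cna = rng.normal(0.0, 0.3, size=(cfg.n_genes, cfg.n_samples))
    conf_mask = np.zeros(cfg.n_genes, bool)
    conf_mask[conf_idx] = True
    cna[conf_mask] += cfg.cna_confounding_strength * B[conf_mask]
    eff_mask = np.zeros(cfg.n_genes, bool)
    eff_mask[effect_idx] = True
    expr = (
        ct_means[:, type_codes]
        + cfg.cna_dosage_coupling * cna
        + cfg.effect_size_sd * (E * eff_mask[:, None])
        + rng.normal(0.0, 1.0, size=(cfg.n_genes, cfg.n_samples))
    )
    expr_df = pd.DataFrame(expr, index=gene_ids, columns=samples)
    cna_df = pd.DataFrame(cna, index=gene_ids, columns=samples)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "has_effect": eff_mask,
            "effect_size_sd": np.where(eff_mask, cfg.effect_size_sd, 0.0),
            "mechanism": [
                mechanism.get(i, "none") if eff_mask[i] else "none"
                for i in range(cfg.n_genes)
            ],
            "cna_confounded": conf_mask,
        }
    )
    return Cohort(
        genes=genes,
        svs=svs,
        expr=expr_df,
        cna=cna_df,
        sample_annotation=annot,
        enhancers=enhancers,
        tads=tads,
        fusions=fusions,
        truth=truth,
        config=cfg,
    )


PRESETS = {
    "null": dict(frac_genes_with_effect=0.0, frac_genes_cna_confounded=0.0),
    "signal": dict(),
    # mechanism presets plant recurrent events (15% of the cohort per gene)
    # so the mechanism-driven over-expression dominates background breaks
    "hijack": dict(frac_hijack_mechanism=1.0, altered_frac=0.15),
    "tad": dict(frac_tad_mechanism=1.0, altered_frac=0.15),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study conditions: null / signal / hijack / tad."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every input file the pipeline stages consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "svs": outdir / "svs.tsv",
        "genes": outdir / "genes.tsv",
        "expression": outdir / "expression.tsv",
        "cna": outdir / "cna.tsv",
        "samples": outdir / "samples.tsv",
        "enhancers": outdir / "enhancers.bed",
        "tads": outdir / "tads.bed",
        "truth": outdir / "truth.tsv",
    }
    svio.write_sv_table(cohort.svs, paths["svs"])
    svio.write_gene_table(cohort.genes, paths["genes"])
    svio.write_matrix(cohort.expr, paths["expression"])
    svio.write_matrix(cohort.cna, paths["cna"])
    svio.write_sample_annotation(cohort.sample_annotation, paths["samples"])
    svio.write_bed_intervals(cohort.enhancers, paths["enhancers"])
    svio.write_bed_intervals(cohort.tads, paths["tads"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if cohort.fusions is not None:
        paths["fusions"] = outdir / "fusions.tsv"
        cohort.fusions.to_csv(paths["fusions"], sep="\t", index=False)
    return paths
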