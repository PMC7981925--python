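# Methods

## Coordinates and input conventions

All internal coordinates are 0-based half-open (BED convention). The SV
table is the one place where 1-based caller coordinates enter; positions
are converted once at read time and never again. Chromosome names are
normalised to the `chr`-prefixed dialect (`MT`/`M` → `chrM`) because SV
tables, gene tables and regulatory BEDs routinely come from sources that
disagree. SVs whose two breakpoints carry identical coordinates hold no
positional information and are dropped with a logged warning. When the SV
table has no id column, ids are assigned from row order, so duplicated
rows remain distinct records (and leave the binary matrix unchanged).

Point-to-interval distances use the gap convention: a point inside or
touching a half-open interval is at distance 0, otherwise the distance is
`start − pos` (left) or `pos − end` (right). An enhancer whose half-open
end sits 10 kb before a TSS is 10,000 bp away.

## Region windows and the breakpoint matrix

Four windows are defined per gene: 100 kb upstream, 100 kb downstream,
the gene body, and the gene ± 1 Mb flank. Upstream/downstream are
strand-aware ("upstream" is biologically strand-relative, although the
underlying convention is not universal across tools — this is a deliberate
design choice). Windows are clipped at coordinate 0.

The unweighted matrix entry is 1 when at least one breakpoint of any SV of
the sample falls in the window; both breakpoints of every SV are tested
independently. The cohort (matrix columns) is fixed by the sample
annotation, so samples without SVs keep all-zero columns rather than
disappearing.

The distance metric for the 1 Mb flank window is a linear decay,
`w = 1 − d / 1 Mb`, with `d = 0` inside the gene body and otherwise the
distance to the nearer of the two body edges; the entry is the per-sample
maximum over breakpoints. The linear form is the simplest function with
the two required properties — full weight at the gene, non-zero influence
anywhere within 1 Mb — and the symmetric `d` matches a flank defined on
both sides. A breakpoint exactly at the left 1 Mb edge is in-window with
weight 0 (half-open windows; the formula handles the boundary).

Gene-to-SV association lists keep exactly one breakpoint per
(gene, sample): the one closest to the strand-aware TSS, with ties broken
to the lower genomic coordinate and then the lexicographically smaller SV
id, so output is deterministic. The mate is flagged *distal* when it lies
on another chromosome or outside the gene's 1 Mb flank.

## Per-gene linear screen

Each gene is fitted by OLS (statsmodels):
`expr ~ 1 + sv + cancer_type [+ cna]`, with the reference cancer-type
level dropped and any further collinear indicator removed
deterministically in level order. Two model families are fitted per run —
with and without the gene-level copy-number covariate — and FDR is
computed separately per family, because they answer different questions
(the CNA-corrected family isolates dosage-independent association).
Samples missing expression or CNA for a gene are dropped for that gene's
fit only; cancer types with a single sample are retained (their indicator
absorbs one observation). Genes whose breakpoint row is constant, or
altered in fewer than `min_altered_samples` samples (default 1, i.e. no
filter), are skipped and excluded from the FDR family. Technical batch
correction of expression/CNA is the user's responsibility upstream of the
screen.

q-values follow Storey–Tibshirani: `pi0(λ) = #{p > λ} / (m(1 − λ))` on
the λ grid 0.05–0.95 (step 0.05), smoothed by a quadratic least-squares
fit and evaluated at the largest λ, clamped to (0, 1]. The quadratic has
three parameters — the effective degrees of freedom of the df = 3
smoothing spline used in the original formulation — and behaves
equivalently on null data while avoiding a spline-df emulation. With
fewer than 4 usable grid points, or a non-positive smoothed value, pi0
falls back to 1, which makes the q-values exactly Benjamini–Hochberg. The
endpoint pi0 estimate is noisy below a few thousand tests (roughly ±0.1
at m = 1000); calibration checks therefore pool p-values across several
null screens before estimating pi0.

## Over-expression rule

A sample over-expresses a gene when its expression exceeds the gene's
cross-sample median by more than 0.4 cross-sample standard deviations
(SD with ddof = 1). "Over-expressed pairs" used by the mechanism
enrichment analyses additionally require the gene to be screen-significant
(q < 0.10 in the 1 Mb-window CNA-corrected family when CNA is available).

## Enhancer hijacking

For an association with a distal mate, the rearrangement is modelled as
fusing the mate's neighbourhood next to the near breakpoint, so the
repositioned gene–enhancer distance is
`d_new = d(near bp, TSS) + d(mate bp, nearest enhancer within 1 Mb)`.
This is the geometry consistent with scanning "1 Mb from the other
breakpoint" while requiring the enhancer to land "within 500 kb of the
gene". An event requires `d_new ≤ 500 kb` and `d_new < d_native`, where
`d_native` is the distance from the TSS to the closest enhancer
overlapping the 1 Mb window upstream of the unaltered gene (nearest-edge
distance; infinite when none). The upstream restriction applies to the
native scan only — the near breakpoint may sit anywhere in the gene's
1 Mb flank — and enhancer orientation is ignored (enhancers act
orientation-independently).

## TAD disruption

Each breakpoint is assigned to the TAD containing it (half-open
containment); nested annotations resolve to the smallest containing TAD
(most specific). Same TAD → preserving; different TADs, including
different chromosomes → disrupting; either breakpoint in a gap →
unassigned. Unassigned is a genuine third class because real TAD BEDs do
not tile the genome.

**Enrichment is computed at the association level**, comparing the
disruption rate of associations whose (gene, sample) pair is
over-expressed against the remaining associations — not against all SVs
genome-wide. The genome-wide comparison is structurally confounded: a
translocation has two independent chances to land near a gene and is
almost always disrupting, so the gene-linked subset over-samples
translocations even when no mechanism is at work (on mechanism-free
synthetic cohorts the genome-wide version rejects a true null in half the
runs). The association-level comparison is exchangeable under the null
and verified to give uniform p-values on mechanism-free cohorts. Hijack
enrichment is analogous: event rate among over-expressed calls versus the
remaining distal-mate calls. Both use Pearson chi-squared (1 df, no
continuity correction); a degenerate margin returns p = 1.

Known limitation: calls cluster within genes and samples (one significant
gene contributes many associations), and the chi-squared test assumes
independent units, so the enrichment p-values are mildly anti-conservative
under the null. At the calibration sizes used here the deviation is small
(uniformity holds by KS test across 50 seeds), but on cohorts with very
large per-gene clusters the p-values should be read qualitatively.

## Fusion corroboration

A fusion candidate (5' gene, 3' gene, sample) has SV support when the
sample carries a breakpoint inside one or both gene bodies (body only —
nearby breakpoints do not count). The high-expression flag is rule 1 OR
rule 2: (1) for fusions seen in ≤ 2 samples (inclusive boundary), every
harbouring sample over-expresses at least one partner by the 0.4 SD rule;
(2) either partner has p < 0.01 with positive t in the CNA-corrected
family for the distance-weighted 1 Mb window or the (binary) gene-body
window. Recurrence is counted on the unordered pair; 5'/3' order is kept
for reporting. Support and expression flags are independent annotations,
so the tiers (no support / SV support / SV support + high expression)
nest.

## Synthetic cohorts

The generator produces every input the pipeline consumes plus a truth
table, deterministically per seed. The genome is 4 chromosomes × 60 Mb;
TADs tile each chromosome with lengths 0.6–1.2 Mb separated by 20–80 kb
gaps (so TAD gaps and chromosome ends exercise the unassigned class);
enhancers (2 kb) are scattered at 3 per Mb; genes are 20–150 kb, placed
uniformly with a 1.5 Mb margin, random strand. Samples are assigned
round-robin to cancer types.

Background SVs (default 8 per sample) have a uniform first breakpoint and
a mate that is 70% short intrachromosomal (50–500 kb) / 30% translocation,
approximating the somatic SV spectrum. Expression is
`cancer-type mean (SD 0.3) + 0.5·CNA + effect + N(0,1)` on the log scale —
Gaussian noise matching the OLS screen's assumptions, with the effect in
units of the unit residual SD. For a mechanism-free effect gene (default:
5% of genes, +2 SD) the effect applies to every sample with a breakpoint
in the gene's 1 Mb flank — the generative model the screen assumes, so
recovery tests measure the screen rather than model mismatch. CNA
confounding is planted in a disjoint 5% of genes as focal amplification:
altered samples gain +3 copy-number units (coupling 0.5 into expression)
with no direct SV effect, so these genes are significant without the CNA
covariate and drop out with it.

Mechanism presets shape the planted SVs and tie the expression effect to
them specifically (only planted-SV samples are shifted), so
over-expression traces the mechanism geometry:

- `hijack`: planted SVs are translocations placed 10–300 kb upstream of
  the TSS whose mate lands 5–100 kb from a planted enhancer, while the
  gene's own ±1 Mb neighbourhood is cleared of enhancers — a callable
  hijack geometry with no native competitor.
- `tad`: planted SVs span a TAD boundary (both breakpoints in different
  TADs of the gene's chromosome).
- Mechanism presets plant events in 15% of the cohort per gene (recurrent
  mechanism events), versus 5% for mechanism-free effects.

What the generator does **not** emulate: realistic SV type spectra beyond
the two-class mix, karyotype-scale aneuploidy, expression heavy tails or
zero inflation, batch effects, hotspot clustering of breakpoints, and
tissue-specific enhancer activity. Passing calibration and recovery tests
on these cohorts shows the statistics behave as designed under their own
assumptions; it does not certify performance on real data with those
additional features.

## Problem sizes used in the checks

Calibration and recovery checks run at: null/signal cohorts of 1000 genes
× 200 samples × 1600 SVs (five pooled null seeds for pi0/type-I error);
mechanism-positive cohorts of 300 genes × 120 samples × 960 SVs; and
mechanism-free null-uniformity cohorts of 300 genes × 60 samples × 480
SVs across 50 seeds — the smaller cohort keeps per-gene call clusters
small so the chi-squared independence assumption holds to good
approximation. Oracle-equivalence checks use 100 randomised small
instances per geometry engine against brute-force double loops, and the
OLS path is checked against an explicit normal-equations solver to 1e-8
on 100 random instances.

## Numerical and degenerate-input choices

- Equal TSS distances break to lower coordinate, then SV id.
- Empty gene set or cohort: hard error; unknown samples in the SV table
  are ignored (the cohort is authoritative).
- All-missing expression rows are skipped, not errors; sample-set
  mismatches between matrices are hard errors.
- `chisq_2x2` returns (0, 1) on a zero margin instead of raising, because
  enrichment on degenerate cohorts carries no evidence either way.
- Storey q-values cap at 1 and are monotone in p by the cumulative-min
  construction; `pi0 = 1` reproduces Benjamini–Hochberg exactly.
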