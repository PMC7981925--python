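"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes results from first principles (double loops,
direct arithmetic, explicit normal equations) without touching the
package's interval indexes or statsmodels, so agreement is meaningful.
"""

import math

import numpy as np
import scipy.stats as st


def window_bounds(gene, window_name, size):
    """Half-open window interval computed directly from the definitions."""
    if window_name == "body":
        lo, hi = gene.start, gene.end
    elif window_name == "flank":
        lo, hi = gene.start - size, gene.end + size
    elif window_name == "up":
        lo, hi = (gene.start - size, gene.start) if gene.strand == "+" else (gene.end, gene.end + size)
    elif window_name == "down":
        lo, hi = (gene.end, gene.end + size) if gene.strand == "+" else (gene.start - size, gene.start)
    else:
        raise ValueError(window_name)
    return max(lo, 0), max(hi, 0)


def brute_matrix(genes, samples, svs, window_name, size, weighted=False):
    """O(genes x breakpoints) double loop over every (gene, breakpoint)."""
    out = np.zeros((len(genes), len(samples)))
    s_index = {s: j for j, s in enumerate(samples)}
    for i, gene in enumerate(genes):
        lo, hi = window_bounds(gene, window_name, size)
        for sv in svs:
            if sv.sample_id not in s_index:
                continue
            j = s_index[sv.sample_id]
            for bp in (sv.bp1, sv.bp2):
                if bp.chrom != gene.chrom or not (lo <= bp.pos < hi):
                    continue
                if weighted:
                    if gene.start <= bp.pos < gene.end:
                        d = 0
                    else:
                        d = min(abs(bp.pos - gene.start), abs(bp.pos - gene.end))
                    out[i, j] = max(out[i, j], 1.0 - d / size)
                else:
                    out[i, j] = 1.0
    return out


def brute_tad_class(sv, tads):
    """Linear containment scan; smallest containing TAD wins."""

    def assign(chrom, pos):
        best = None
        for r in tads.itertuples(index=False):
            if r.chrom == chrom and r.start <= pos < r.end:
                if best is None or (r.end - r.start, r.start) < (best[2] - best[1], best[1]):
                    best = (r.chrom, r.start, r.end)
        return best

    t1 = assign(sv.bp1.chrom, sv.bp1.pos)
    t2 = assign(sv.bp2.chrom, sv.bp2.pos)
    if t1 is None or t2 is None:
        return "unassigned"
    return "preserving" if t1 == t2 else "disrupting"


def brute_hijack_event(gene, near_pos, mate_chrom, mate_pos, enhancers,
                       scan=1_000_000, max_dist=500_000):
    """All-pairs scan over enhancers, distances computed inline."""

    def dist(pos, s, e):
        return max(s - pos, pos - e, 0)

    tss = gene.start if gene.strand == "+" else gene.end - 1
    d_enh = math.inf
    for r in enhancers.itertuples(index=False):
        if r.chrom != mate_chrom:
            continue
        d = dist(mate_pos, r.start, r.end)
        if d <= scan:
            d_enh = min(d_enh, d)
    d_native = math.inf
    for r in enhancers.itertuples(index=False):
        if r.chrom != gene.chrom:
            continue
        if gene.strand == "+":
            wlo, whi = tss - scan, tss + 1
        else:
            wlo, whi = tss, tss + scan + 1
        if r.start < whi and r.end > wlo:
            d_native = min(d_native, dist(tss, r.start, r.end))
    d_new = abs(near_pos - tss) + d_enh
    return math.isfinite(d_enh) and d_new <= max_dist and d_new < d_native


def brute_ols_sv(y, sv, cancer_type, cna=None):
    """Normal-equations OLS: (beta, t, p) for the sv coefficient.

    Design: intercept + sv + one indicator per non-reference cancer-type
    level (sorted order) [+ cna].  Valid for full-rank instances.
    """
    n = len(y)
    cols = [np.ones(n), np.asarray(sv, float)]
    levels = sorted(set(cancer_type))
    for lev in levels[1:]:
        cols.append((np.asarray(cancer_type) == lev).astype(float))
    if cna is not None:
        cols.append(np.asarray(cna, float))
    X = np.column_stack(cols)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2 * st.t.sf(abs(t), df)
    return beta[1], t, p


def bh_adjust(p):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj
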