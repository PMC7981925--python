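"""Per-gene linear modelling of expression against breakpoint pattern.

For each gene, expression across the cohort is regressed on the gene's
breakpoint-matrix row with cancer-type indicators as covariates and,
optionally, the gene's copy-number value:

    expr ~ intercept + sv + cancer_type [+ cna]

The two-sided t-test on the ``sv`` coefficient measures whether expression
tracks nearby breakpoints; the CNA-corrected family asks whether the
association survives dosage, which is the variant of primary interest
because rearrangements travel with widespread copy-number change.
Multiple testing is controlled with Storey–Tibshirani q-values computed
within each (window, model) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .matrix import BreakpointMatrix
from .model import Config, RegionWindow, SampleAnnotation

STATUS_OK = "ok"
STATUS_CONSTANT = "skipped_constant"
STATUS_MIN_ALT = "skipped_min_alt"

MODEL_TYPE_ONLY = "type_only"
MODEL_TYPE_PLUS_CNA = "type_plus_cna"


@dataclass
class AssociationResult:
    gene_id: str
    window: RegionWindow
    model: str
    beta_sv: float
    t_stat: float
    p_value: float
    n_altered: int
    status: str
    q_value: float = np.nan


def _design_matrix(
    sv: np.ndarray, cancer_type: np.ndarray, cna: np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + sv + cancer-type indicators (+ cna), full column rank.

    The first level (sorted order) is the dropped reference; any indicator
    that makes the matrix rank-deficient is dropped next, in level order,
    so the fit is deterministic under collinearity.
    """
    n = len(sv)
    levels = sorted(pd.unique(cancer_type))
    dummy_cols = []
    dummy_names = []
    for lev in levels[1:]:
        dummy_cols.append((cancer_type == lev).astype(float))
        dummy_names.append(f"type[{lev}]")
    base = [np.ones(n), sv.astype(float)]
    names = ["intercept", "sv"]
    if cna is not None:
        tail_cols: list[np.ndarray] = [cna.astype(float)]
        tail_names = ["cna"]
    else:
        tail_cols, tail_names = [], []
    X = np.column_stack(base + dummy_cols + tail_cols)
    names_all = names + dummy_names + tail_names
    # drop redundant cancer-type indicators deterministically (level order)
    while np.linalg.matrix_rank(X) < X.shape[1]:
        n_dummies = X.shape[1] - 2 - len(tail_names)
        for j in range(2, 2 + n_dummies):
            trial = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(trial) == np.linalg.matrix_rank(X):
                X = trial
                del names_all[j]
                break
        else:
            break
    return X, names_all


def fit_gene_model(
    expr_row: pd.Series,
    sv_row: pd.Series,
    cancer_type: pd.Series,
    cna_row: pd.Series | None = None,
    config: Config | None = None,
    gene_id: str = "",
    window: RegionWindow = RegionWindow.FLANK_1MB,
) -> AssociationResult:
    """OLS fit for one gene; reports beta / t / two-sided p on ``sv``.

    Samples with a missing expression (or CNA) value are dropped for this
    gene only.  Genes whose breakpoint row is constant, or altered in fewer
    than ``min_altered_samples`` samples, are skipped rather than fitted.
    """
    config = config or Config()
    model_name = MODEL_TYPE_ONLY if cna_row is None else MODEL_TYPE_PLUS_CNA
    if not expr_row.index.equals(sv_row.index) or not expr_row.index.equals(
        cancer_type.index
    ):
        raise ValueError("expression, breakpoint and annotation sample sets differ")
    if cna_row is not None and not expr_row.index.equals(cna_row.index):
        raise ValueError("expression and CNA sample sets differ")

    mask = expr_row.notna().to_numpy()
    if cna_row is not None:
        mask &= cna_row.notna().to_numpy()
    y = expr_row.to_numpy(dtype=float)[mask]
    sv = sv_row.to_numpy(dtype=float)[mask]
    ct = cancer_type.to_numpy()[mask]
    cna = cna_row.to_numpy(dtype=float)[mask] if cna_row is not None else None

    def skipped(status: str, n_alt: int) -> AssociationResult:
        return AssociationResult(
            gene_id, window, model_name, np.nan, np.nan, np.nan, n_alt, status
        )

    n_altered = int(np.count_nonzero(sv))
    if len(y) == 0 or np.ptp(sv) == 0:
        return skipped(STATUS_CONSTANT, n_altered)
    if n_altered < config.min_altered_samples:
        return skipped(STATUS_MIN_ALT, n_altered)

    X, names = _design_matrix(sv, ct, cna)
    if len(y) <= X.shape[1]:
        return skipped(STATUS_CONSTANT, n_altered)
    fit = sm.OLS(y, X).fit()
    j = names.index("sv")
    return AssociationResult(
        gene_id=gene_id,
        window=window,
        model=model_name,
        beta_sv=float(fit.params[j]),
        t_stat=float(fit.tvalues[j]),
        p_value=float(fit.pvalues[j]),
        n_altered=n_altered,
        status=STATUS_OK,
    )


def estimate_pi0(
    p_values: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Storey–Tibshirani pi0: proportion of true nulls.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` is evaluated on the
    0.05..0.95 grid (step 0.05) and smoothed with a quadratic least-squares
    fit — three parameters, the effective df of the original df=3 smoothing
    spline — whose value at the largest lambda is the estimate, clamped to
    (0, 1].  With fewer than 4 usable grid points (or a degenerate smooth)
    the estimate falls back to 1, which reduces the q-values to
    Benjamini–Hochberg.
    """
    p = _validated_p(p_values)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_raw = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    usable = pi0_raw > 0
    if usable.sum() < 4:
        return 1.0
    lam_u, pi0_u = lambdas[usable], pi0_raw[usable]
    coeffs = np.polynomial.polynomial.polyfit(lam_u, pi0_u, deg=2)
    pi0 = float(np.polynomial.polynomial.polyval(lam_u.max(), coeffs))
    if pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def _validated_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def storey_qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """q-values: q_(i) = min_{j>=i} pi0 * m * p_(j) / j over sorted p.

    With ``pi0`` forced to 1 this is exactly the Benjamini–Hochberg
    adjustment; by default pi0 is estimated with :func:`estimate_pi0`.
    """
    p = _validated_p(p_values)
    m = len(p)
    if m == 0:
        return p
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_association_screen(
    expr_matrix: pd.DataFrame,
    bp_matrices: BreakpointMatrix | list[BreakpointMatrix],
    sample_annot: list[SampleAnnotation] | pd.Series,
    cna_matrix: pd.DataFrame | None = None,
    config: Config | None = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Screen every gene in every supplied breakpoint matrix.

    Fits the cancer-type-only family and, when a CNA matrix is supplied,
    the CNA-corrected family as well.  q-values are computed within each
    (window, model) family over the ``ok`` genes only; ``significant``
    marks ``q < fdr_threshold``.  Per-gene fits are embarrassingly
    parallel: with ``n_jobs > 1`` they run on joblib workers and the
    result is identical to the serial order.
    """
    config = config or Config()
    if isinstance(bp_matrices, BreakpointMatrix):
        bp_matrices = [bp_matrices]
    if isinstance(sample_annot, pd.Series):
        ct = sample_annot.astype(str)
    else:
        ct = pd.Series(
            {a.sample_id: a.cancer_type for a in sample_annot}, dtype=str
        )
    samples = [s for s in expr_matrix.columns if s in set(ct.index)]
    if len(samples) < 2:
        raise ValueError("need at least 2 annotated samples")
    expr = expr_matrix[samples]
    ct = ct.loc[samples]
    cna = cna_matrix[samples] if cna_matrix is not None else None

    tasks = []
    for bpm in bp_matrices:
        bvals = bpm.values.reindex(columns=samples, fill_value=0.0)
        genes = [g for g in expr.index if g in set(bvals.index)]
        models: list[str] = [MODEL_TYPE_ONLY]
        if cna is not None:
            models.append(MODEL_TYPE_PLUS_CNA)
        for model in models:
            for g in genes:
                cna_row = None
                if model == MODEL_TYPE_PLUS_CNA:
                    cna_row = (
                        cna.loc[g]
                        if g in cna.index
                        else pd.Series(np.nan, index=samples)
                    )
                tasks.append((expr.loc[g], bvals.loc[g], cna_row, g, bpm.window))

    def _fit(task):
        expr_row, sv_row, cna_row, g, window = task
        return fit_gene_model(
            expr_row, sv_row, ct, cna_row, config=config, gene_id=g, window=window
        )

    if n_jobs == 1:
        rows = [_fit(t) for t in tasks]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(delayed(_fit)(t) for t in tasks)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "window": [r.window.value for r in rows],
            "model": [r.model for r in rows],
            "beta_sv": [r.beta_sv for r in rows],
            "t_stat": [r.t_stat for r in rows],
            "p_value": [r.p_value for r in rows],
            "n_altered": [r.n_altered for r in rows],
            "status": [r.status for r in rows],
        }
    )
    df["q_value"] = np.nan
    for (_, _), idx in df.groupby(["window", "model"]).groups.items():
        sub = df.loc[idx]
        ok = sub["status"] == STATUS_OK
        if ok.any():
            df.loc[sub.index[ok], "q_value"] = storey_qvalues(
                sub.loc[ok, "p_value"].to_numpy()
            )
    df["significant"] = (df["status"] == STATUS_OK) & (
        df["q_value"] < config.fdr_threshold
    )
    return df


def overlap_fisher(
    n_universe: int, n_set_a: int, n_set_b: int, n_overlap: int
) -> float:
    """One-sided Fisher's exact p for the overlap of two gene sets.

    Upper-tail hypergeometric: P(X >= n_overlap) with X ~
    Hypergeom(n_universe, n_set_a, n_set_b).
    """
    if not (0 <= n_overlap <= min(n_set_a, n_set_b) <= max(n_set_a, n_set_b) <= n_universe):
        raise ValueError("inconsistent overlap counts")
    return float(st.hypergeom.sf(n_overlap - 1, n_universe, n_set_a, n_set_b))


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table.

    Returns (statistic, p).  Degenerate tables (a zero margin) carry no
    evidence of association and return (0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 and non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 0.0, 1.0
    stat, p, _, _ = st.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def overexpression_flags(
    expr_matrix: pd.DataFrame, sd_threshold: float = 0.4
) -> pd.DataFrame:
    """Boolean gene x sample frame: expression > ``sd_threshold`` cross-sample
    SDs above the gene's cross-sample median."""
    med = expr_matrix.median(axis=1)
    sd = expr_matrix.std(axis=1, ddof=1)
    z = expr_matrix.sub(med, axis=0).div(sd.replace(0, np.nan), axis=0)
    return z > sd_threshold
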