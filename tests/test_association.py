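import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from svgex.association import (
    MODEL_TYPE_ONLY,
    MODEL_TYPE_PLUS_CNA,
    STATUS_CONSTANT,
    STATUS_MIN_ALT,
    chisq_2x2,
    estimate_pi0,
    fit_gene_model,
    overexpression_flags,
    overlap_fisher,
    run_association_screen,
    storey_qvalues,
)
from svgex.matrix import BreakpointMatrix
from svgex.model import Config, RegionWindow, SampleAnnotation

from .oracles import bh_adjust, brute_ols_sv


def series(vals, samples):
    return pd.Series(vals, index=samples, dtype=float)


class TestFitGeneModel:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(60)]
        sv = np.zeros(60)
        sv[:10] = 1
        expr = 2.0 * sv + rng.normal(0, 0.01, 60)
        res = fit_gene_model(
            series(expr, samples), series(sv, samples),
            pd.Series(["a"] * 60, index=samples),
        )
        assert res.status == "ok"
        assert res.t_stat > 50 and res.p_value < 1e-20
        assert res.beta_sv == pytest.approx(2.0, abs=0.02)

    def test_constant_sv_row_skipped(self):
        samples = ["s1", "s2", "s3", "s4"]
        res = fit_gene_model(
            series([1, 2, 3, 4], samples), series([0, 0, 0, 0], samples),
            pd.Series(["a"] * 4, index=samples),
        )
        assert res.status == STATUS_CONSTANT
        assert np.isnan(res.t_stat)

    def test_min_altered_filter(self):
        samples = [f"s{i}" for i in range(20)]
        sv = np.zeros(20)
        sv[0] = 1
        res = fit_gene_model(
            series(np.arange(20), samples), series(sv, samples),
            pd.Series(["a"] * 20, index=samples),
            config=Config(min_altered_samples=3),
        )
        assert res.status == STATUS_MIN_ALT
        assert res.n_altered == 1

    def test_all_missing_expression_skips_not_crashes(self):
        samples = ["s1", "s2", "s3"]
        res = fit_gene_model(
            series([np.nan] * 3, samples), series([1, 0, 0], samples),
            pd.Series(["a"] * 3, index=samples),
        )
        assert res.status == STATUS_CONSTANT

    def test_sample_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="sample"):
            fit_gene_model(
                series([1, 2], ["s1", "s2"]), series([1, 0], ["s1", "s3"]),
                pd.Series(["a", "a"], index=["s1", "s2"]),
            )

    def test_matches_normal_equations_oracle(self, rng):
        samples = [f"s{i}" for i in range(40)]
        for _ in range(25):
            sv = (rng.random(40) < 0.3).astype(float)
            if sv.std() == 0:
                continue
            ct = np.where(rng.random(40) < 0.5, "typeA", "typeB")
            cna = rng.normal(0, 1, 40)
            y = 0.5 * sv + 0.3 * cna + rng.normal(0, 1, 40)
            res = fit_gene_model(
                series(y, samples), series(sv, samples),
                pd.Series(ct, index=samples), series(cna, samples),
            )
            beta, t, p = brute_ols_sv(y, sv, ct, cna)
            assert res.beta_sv == pytest.approx(beta, abs=1e-8)
            assert res.t_stat == pytest.approx(t, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_single_sample_cancer_type_retained(self, rng):
        samples = [f"s{i}" for i in range(21)]
        ct = np.array(["a"] * 10 + ["b"] * 10 + ["solo"])
        sv = (rng.random(21) < 0.4).astype(float)
        sv[0] = 1
        y = sv + rng.normal(0, 1, 21)
        res = fit_gene_model(series(y, samples), series(sv, samples),
                             pd.Series(ct, index=samples))
        beta, t, p = brute_ols_sv(y, sv, ct)
        assert res.status == "ok"
        assert res.t_stat == pytest.approx(t, abs=1e-8)

    def test_missing_values_dropped_per_gene(self, rng):
        samples = [f"s{i}" for i in range(30)]
        sv = (rng.random(30) < 0.4).astype(float)
        y = sv * 0.8 + rng.normal(0, 1, 30)
        y_missing = y.copy()
        y_missing[:5] = np.nan
        res = fit_gene_model(series(y_missing, samples), series(sv, samples),
                             pd.Series(["a"] * 30, index=samples))
        beta, t, p = brute_ols_sv(y[5:], sv[5:], np.array(["a"] * 25))
        assert res.t_stat == pytest.approx(t, abs=1e-8)


class TestStoreyQvalues:
    def test_all_equal_p_gives_pi0_times_p(self):
        p = np.full(50, 0.02)
        q = storey_qvalues(p, pi0=0.8)
        np.testing.assert_allclose(q, 0.8 * 0.02)

    def test_pi0_one_reproduces_benjamini_hochberg(self, rng):
        p = rng.uniform(0.001, 1.0, 500)
        np.testing.assert_allclose(storey_qvalues(p, pi0=1.0), bh_adjust(p), atol=1e-12)

    def test_pi0_near_one_on_uniform_nulls(self):
        for seed in range(5):
            p = np.random.default_rng(seed).uniform(1e-12, 1.0, 2000)
            assert 0.9 <= estimate_pi0(p) <= 1.0

    def test_pi0_below_one_with_dense_signal(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(1e-12, 1, 1000),
                            rng.uniform(1e-12, 0.001, 1000)])
        assert estimate_pi0(p) < 0.75

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 0.0])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])

    @given(hst.lists(hst.floats(1e-9, 1.0), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_q_monotone_in_p_and_bounded(self, p_list):
        p = np.array(p_list)
        q = storey_qvalues(p, pi0=1.0)
        assert np.all(q <= 1.0) and np.all(q > 0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestOverlapFisher:
    def test_reported_cohort_overlap_example(self):
        # 344 of 1249 screen-significant genes among 4451 hotspot genes,
        # 20153-gene universe
        p = overlap_fisher(20153, 1249, 4451, 344)
        assert p == pytest.approx(1.6e-6, rel=0.05)

    def test_complete_overlap_closed_form(self):
        # overlap = |A| = |B| = 3: p = C(3,3)*C(17,0)/C(20,3)
        from math import comb

        p = overlap_fisher(20, 3, 3, 3)
        assert p == pytest.approx(comb(3, 3) * comb(17, 0) / comb(20, 3), rel=1e-12)

    def test_expected_overlap_is_central(self):
        # E[overlap] = 100*100/1000 = 10; observing exactly it is not surprising
        p = overlap_fisher(1000, 100, 100, 10)
        assert 0.4 < p < 0.7

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_fisher(100, 10, 20, 15)


class TestChisq:
    def test_independent_table_p_one(self):
        stat, p = chisq_2x2([[10, 10], [10, 10]])
        assert stat == 0 and p == 1

    def test_hand_computed_statistic(self):
        stat, p = chisq_2x2([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_agrees_with_fisher_on_large_balanced_tables(self):
        import scipy.stats as st

        _, p_chi = chisq_2x2([[200, 100], [120, 180]])
        p_fisher = st.fisher_exact([[200, 100], [120, 180]])[1]
        assert np.log10(p_chi) == pytest.approx(np.log10(p_fisher), abs=0.5)

    def test_degenerate_margin_returns_one(self):
        assert chisq_2x2([[0, 0], [5, 10]])[1] == 1.0


@pytest.fixture(scope="module")
def small_screen():
    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(50)]
    genes = [f"g{i}" for i in range(30)]
    bp = pd.DataFrame((rng.random((30, 50)) < 0.2).astype(float),
                      index=genes, columns=samples)
    bp.iloc[5] = 0.0  # constant row -> skipped
    expr = pd.DataFrame(rng.normal(0, 1, (30, 50)), index=genes, columns=samples)
    expr.iloc[0] += 3.0 * bp.iloc[0]  # one strong planted gene
    annot = [SampleAnnotation(s, "t1" if i < 25 else "t2")
             for i, s in enumerate(samples)]
    cna = pd.DataFrame(rng.normal(0, 0.3, (30, 50)), index=genes, columns=samples)
    bpm = BreakpointMatrix(bp, RegionWindow.FLANK_1MB, False)
    return run_association_screen(expr, bpm, annot, cna)


class TestScreen:

    def test_two_model_families_fit(self, small_screen):
        assert set(small_screen["model"]) == {MODEL_TYPE_ONLY, MODEL_TYPE_PLUS_CNA}
        assert (small_screen.groupby("model").size() == 30).all()

    def test_planted_gene_significant_with_positive_t(self, small_screen):
        row = small_screen[(small_screen["gene_id"] == "g0")
                           & (small_screen["model"] == MODEL_TYPE_PLUS_CNA)].iloc[0]
        assert row["significant"] and row["t_stat"] > 0

    def test_skipped_genes_excluded_from_fdr_family(self, small_screen):
        skipped = small_screen[small_screen["gene_id"] == "g5"]
        assert (skipped["status"] == STATUS_CONSTANT).all()
        assert skipped["q_value"].isna().all()

    def test_too_few_samples_hard_error(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["s1"])
        bpm = BreakpointMatrix(expr.copy(), RegionWindow.FLANK_1MB, False)
        with pytest.raises(ValueError):
            run_association_screen(expr, bpm, [SampleAnnotation("s1", "a")])

    def test_permuting_sample_labels_destroys_significance(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(80)]
        sv = (rng.random(80) < 0.15).astype(float)
        expr = 2.0 * sv + rng.normal(0, 1, 80)
        ct = pd.Series(["a"] * 80, index=samples)
        p_perm = []
        for _ in range(30):
            perm = rng.permutation(80)
            res = fit_gene_model(series(expr, samples), series(sv[perm], samples), ct)
            p_perm.append(res.p_value)
        assert np.median(p_perm) > 0.3


def test_parallel_screen_matches_serial(small_screen):
    """Worker partitioning must not change any statistic."""
    rng = np.random.default_rng(11)
    samples = [f"s{i}" for i in range(50)]
    genes = [f"g{i}" for i in range(30)]
    bp = pd.DataFrame((rng.random((30, 50)) < 0.2).astype(float),
                      index=genes, columns=samples)
    bp.iloc[5] = 0.0
    expr = pd.DataFrame(rng.normal(0, 1, (30, 50)), index=genes, columns=samples)
    expr.iloc[0] += 3.0 * bp.iloc[0]
    annot = [SampleAnnotation(s, "t1" if i < 25 else "t2")
             for i, s in enumerate(samples)]
    cna = pd.DataFrame(rng.normal(0, 0.3, (30, 50)), index=genes, columns=samples)
    bpm = BreakpointMatrix(bp, RegionWindow.FLANK_1MB, False)
    parallel = run_association_screen(expr, bpm, annot, cna, n_jobs=2)
    pd.testing.assert_frame_equal(parallel, small_screen)


def test_overexpression_rule_is_median_plus_sd_scaled():
    expr = pd.DataFrame(
        [[0.0, 0.0, 0.0, 10.0]], index=["g"], columns=list("abcd")
    )
    flags = overexpression_flags(expr, sd_threshold=0.4)
    med, sd = 0.0, expr.loc["g"].std(ddof=1)
    assert bool(flags.at["g", "d"]) == ((10.0 - med) / sd > 0.4)
    assert not flags.loc["g", ["a", "b", "c"]].any()
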