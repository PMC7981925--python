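import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svgex.matrix import (
    breakpoint_weight,
    build_matrix,
    distance_to_gene,
    gene_sv_associations,
    window_interval,
)
from svgex.model import Config, GeneModel, RegionWindow

from .conftest import make_sv, random_instance
from .oracles import brute_matrix


class TestWindowInterval:
    def test_upstream_clipped_at_origin(self):
        g = GeneModel("g", "chr1", 10_000, 20_000, "+")
        assert window_interval(g, RegionWindow.UPSTREAM_100KB, 100_000) == ("chr1", 0, 10_000)

    def test_upstream_minus_strand_mirrors(self):
        g = GeneModel("g", "chr1", 10_000, 20_000, "-")
        assert window_interval(g, RegionWindow.UPSTREAM_100KB, 100_000) == (
            "chr1", 20_000, 120_000)

    def test_flank_spans_body_plus_both_sides(self):
        g = GeneModel("g", "chr2", 5_000_000, 5_010_000, "+")
        assert window_interval(g, RegionWindow.FLANK_1MB, 1_000_000) == (
            "chr2", 4_000_000, 6_010_000)

    def test_downstream_strand_aware(self):
        plus = GeneModel("g", "chr1", 10_000, 20_000, "+")
        minus = GeneModel("g", "chr1", 10_000, 20_000, "-")
        assert window_interval(plus, RegionWindow.DOWNSTREAM_100KB, 5_000) == (
            "chr1", 20_000, 25_000)
        assert window_interval(minus, RegionWindow.DOWNSTREAM_100KB, 5_000) == (
            "chr1", 5_000, 10_000)


class TestBreakpointWeight:
    def test_boundary_values(self):
        assert breakpoint_weight(0, 1_000_000) == 1.0
        assert breakpoint_weight(1_000_000, 1_000_000) == 0.0
        assert breakpoint_weight(250_000, 1_000_000) == 0.75

    def test_outside_window_is_an_error(self):
        with pytest.raises(ValueError):
            breakpoint_weight(1_000_001, 1_000_000)

    @given(st.integers(0, 999_999))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing(self, d):
        assert breakpoint_weight(d, 1_000_000) > breakpoint_weight(d + 1, 1_000_000)


class TestBuildMatrix:
    def test_body_hit_and_window_specificity(self):
        g = GeneModel("g", "chr1", 10_000, 20_000, "+")
        inside = [make_sv("a", "S1", "chr1", 15_000, "chr9", 1)]
        upstream = [make_sv("b", "S1", "chr1", 9_000, "chr9", 1)]
        assert build_matrix([g], inside, RegionWindow.GENE_BODY).values.at["g", "S1"] == 1
        assert build_matrix([g], upstream, RegionWindow.GENE_BODY).values.at["g", "S1"] == 0
        assert build_matrix([g], upstream, RegionWindow.UPSTREAM_100KB).values.at["g", "S1"] == 1

    def test_cohort_keeps_all_zero_columns(self):
        g = GeneModel("g", "chr1", 10_000, 20_000, "+")
        svs = [make_sv("a", "S1", "chr1", 15_000, "chr9", 1)]
        m = build_matrix([g], svs, RegionWindow.GENE_BODY, samples=["S1", "S2"])
        assert list(m.values.columns) == ["S1", "S2"]
        assert m.values.at["g", "S2"] == 0

    def test_empty_inputs_are_hard_errors(self):
        g = GeneModel("g", "chr1", 10, 20, "+")
        with pytest.raises(ValueError):
            build_matrix([], [make_sv("a", "S1", "chr1", 15, "chr9", 1)],
                         RegionWindow.GENE_BODY)
        with pytest.raises(ValueError):
            build_matrix([g], [], RegionWindow.GENE_BODY)

    @pytest.mark.parametrize("window,wname", [
        (RegionWindow.GENE_BODY, "body"),
        (RegionWindow.UPSTREAM_100KB, "up"),
        (RegionWindow.DOWNSTREAM_100KB, "down"),
        (RegionWindow.FLANK_1MB, "flank"),
    ])
    def test_matches_brute_force_double_loop(self, window, wname, rng):
        cfg = Config()
        for _ in range(10):
            genes, samples, svs = random_instance(rng, n_genes=50, n_samples=20, n_svs=200)
            got = build_matrix(genes, svs, window, cfg, samples=samples).values
            expected = brute_matrix(genes, samples, svs, wname, cfg.window_size(window))
            np.testing.assert_array_equal(got.to_numpy(), expected)

    def test_weighted_matches_brute_force(self, rng):
        cfg = Config()
        for _ in range(5):
            genes, samples, svs = random_instance(rng)
            got = build_matrix(genes, svs, RegionWindow.FLANK_1MB, cfg,
                               samples=samples, weighted=True).values
            expected = brute_matrix(genes, samples, svs, "flank", 1_000_000, weighted=True)
            np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)

    def test_weighted_positive_iff_unweighted_one_except_zero_weight_edge(self, rng):
        genes, samples, svs = random_instance(rng, n_svs=150)
        binary = build_matrix(genes, svs, RegionWindow.FLANK_1MB, samples=samples).values
        weighted = build_matrix(genes, svs, RegionWindow.FLANK_1MB, samples=samples,
                                weighted=True).values
        # weighted > 0 implies binary 1; binary 1 with weighted 0 only at the edge
        assert ((weighted.to_numpy() > 0) <= (binary.to_numpy() == 1)).all()

    def test_invariant_to_sv_and_sample_order(self, rng):
        genes, samples, svs = random_instance(rng)
        m1 = build_matrix(genes, svs, RegionWindow.FLANK_1MB, samples=samples).values
        m2 = build_matrix(genes, svs[::-1], RegionWindow.FLANK_1MB,
                          samples=samples[::-1]).values
        np.testing.assert_array_equal(m1.to_numpy(), m2[m1.columns].to_numpy())

    def test_nonzero_count_monotone_in_window_size(self, rng):
        genes, samples, svs = random_instance(rng)
        counts = []
        for size in (100_000, 500_000, 1_000_000):
            cfg = Config(window_sizes={RegionWindow.FLANK_1MB: size,
                                       RegionWindow.UPSTREAM_100KB: 100_000,
                                       RegionWindow.DOWNSTREAM_100KB: 100_000,
                                       RegionWindow.GENE_BODY: 0})
            m = build_matrix(genes, svs, RegionWindow.FLANK_1MB, cfg, samples=samples)
            counts.append(m.values.to_numpy().sum())
        assert counts == sorted(counts)

    def test_sv_type_filter(self):
        g = GeneModel("g", "chr1", 10_000, 20_000, "+")
        svs = [make_sv("a", "S1", "chr1", 15_000, "chr9", 1, sv_type="DEL"),
               make_sv("b", "S2", "chr1", 15_000, "chr9", 1, sv_type="TRA")]
        m = build_matrix([g], svs, RegionWindow.GENE_BODY, samples=["S1", "S2"],
                         sv_type="DEL")
        assert m.values.at["g", "S1"] == 1 and m.values.at["g", "S2"] == 0


class TestGeneSvAssociations:
    def test_closest_to_tss_wins(self):
        g = GeneModel("g", "chr1", 1_000_000, 1_050_000, "+")
        far = make_sv("far", "S1", "chr1", 1_000_000 - 80_000, "chr9", 1)
        near = make_sv("near", "S1", "chr1", 1_000_000 - 5_000, "chr9", 1)
        (assoc,) = gene_sv_associations([g], [far, near], RegionWindow.UPSTREAM_100KB)
        assert assoc.sv_id == "near"
        assert assoc.distance_to_gene == 5_000

    def test_tie_breaks_to_lower_coordinate_then_sv_id(self):
        g = GeneModel("g", "chr1", 1_000_000, 1_050_000, "+")
        left = make_sv("z", "S1", "chr1", 1_000_000 - 5_000, "chr9", 1)
        right = make_sv("a", "S1", "chr1", 1_000_000 + 5_000, "chr9", 1)
        (assoc,) = gene_sv_associations([g], [left, right], RegionWindow.FLANK_1MB)
        assert assoc.sv_id == "z"  # equal TSS distance, lower coordinate wins

    def test_mate_distal_for_translocation_and_not_for_local_sv(self):
        g = GeneModel("g", "chr1", 2_000_000, 2_050_000, "+")
        tra = make_sv("t", "S1", "chr1", 2_010_000, "chr9", 500)
        local = make_sv("l", "S2", "chr1", 2_010_000, "chr1", 2_400_000)
        assocs = gene_sv_associations([g], [tra, local], RegionWindow.FLANK_1MB)
        by_sample = {a.sample_id: a for a in assocs}
        assert by_sample["S1"].mate_is_distal is True
        assert by_sample["S2"].mate_is_distal is False

    def test_mate_beyond_flank_window_is_distal(self):
        g = GeneModel("g", "chr1", 2_000_000, 2_050_000, "+")
        sv = make_sv("x", "S1", "chr1", 2_010_000, "chr1", 9_000_000)
        (assoc,) = gene_sv_associations([g], [sv], RegionWindow.FLANK_1MB)
        assert assoc.mate_is_distal is True

    def test_one_association_per_gene_sample(self, rng):
        genes, samples, svs = random_instance(rng)
        assocs = gene_sv_associations(genes, svs, RegionWindow.FLANK_1MB)
        keys = [(a.gene_id, a.sample_id) for a in assocs]
        assert len(keys) == len(set(keys))
        cfg = Config()
        # association exists exactly where the matrix is nonzero
        m = build_matrix(genes, svs, RegionWindow.FLANK_1MB, cfg, samples=samples).values
        nonzero = {(gi, sj) for gi in m.index for sj in m.columns if m.at[gi, sj] > 0}
        assert set(keys) == nonzero


def test_distance_to_gene_zero_inside_body():
    g = GeneModel("g", "chr1", 100, 200, "+")
    assert distance_to_gene(150, g) == 0
    assert distance_to_gene(90, g) == 10
    assert distance_to_gene(260, g) == 60
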