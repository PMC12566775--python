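"""Segment calling, recombination counting, QC filtering, bin harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from callusmap import binmarkers, simdata
from callusmap.binmarkers import (
    QC_SEGMENT_PARAMS,
    SegmentParams,
    call_segments,
    call_segments_all,
    count_recombination_events,
    expected_recombination_count,
    filter_individuals,
    harmonize_bins,
    smooth_calls,
)
from callusmap.core import (
    CODE_AA,
    CODE_AB,
    CODE_BB,
    CODE_NA,
    GeneticMap,
    GenotypeMatrix,
    Segment,
    SegmentSet,
)


def one_ind_matrix(codes, pos_bp=None, chrom="chr1"):
    codes = np.asarray(codes, dtype=np.int8)
    if pos_bp is None:
        pos_bp = np.arange(codes.size) * 1000 + 500
    sites = pd.DataFrame({"chrom": chrom, "pos_bp": pos_bp})
    return GenotypeMatrix(sites, ["x"], codes[:, None])


class TestCallSegments:
    def test_constant_calls_give_one_segment(self):
        m = one_ind_matrix([CODE_AA] * 100)
        segs = call_segments(m, "x").segments
        assert len(segs) == 1
        assert segs[0].genotype == CODE_AA
        assert segs[0].n_support_snps == 100

    def test_single_transition_boundary_at_midpoint(self):
        m = one_ind_matrix([CODE_AA] * 50 + [CODE_BB] * 50)
        segs = call_segments(m, "x").segments
        assert len(segs) == 2
        last_aa, first_bb = 49 * 1000 + 500, 50 * 1000 + 500
        assert segs[0].end_bp == segs[1].start_bp == (last_aa + first_bb + 1) // 2

    def test_isolated_error_smoothed_away(self):
        codes = [CODE_AA] * 50
        codes[25] = CODE_BB
        m = one_ind_matrix(codes)
        segs = call_segments(m, "x", SegmentParams(5, 3)).segments
        assert len(segs) == 1 and segs[0].genotype == CODE_AA

    def test_short_run_absorbed_between_agreeing_flanks(self):
        # window 1 keeps the 2-SNP BB run; min 3 support absorbs it through
        codes = [CODE_AA] * 20 + [CODE_BB] * 2 + [CODE_AA] * 20
        m = one_ind_matrix(codes)
        segs = call_segments(m, "x", SegmentParams(1, 3)).segments
        assert len(segs) == 1
        assert segs[0].n_support_snps == 42

    def test_missing_calls_do_not_break_segments(self):
        codes = ([CODE_AA] * 30 + [CODE_NA] * 10 + [CODE_AA] * 30
                 + [CODE_BB] * 30)
        m = one_ind_matrix(codes)
        segs = call_segments(m, "x").segments
        assert [s.genotype for s in segs] == [CODE_AA, CODE_BB]

    def test_all_missing_chromosome_yields_no_segments(self):
        m = one_ind_matrix([CODE_NA] * 20)
        assert call_segments(m, "x").segments == []

    def test_smoothing_window_must_be_odd(self):
        with pytest.raises(ValueError):
            SegmentParams(4, 3)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=80),
           st.sampled_from([1, 2, 3]))
    @settings(max_examples=60, deadline=None)
    def test_segmentation_idempotent(self, codes, min_snps):
        """Re-segmenting calls reconstructed from segments changes nothing
        (run-length regime; plurality smoothing is only idempotent for
        segments longer than the window, checked separately below)."""
        m = one_ind_matrix(codes)
        params = SegmentParams(1, min_snps)
        segs1 = call_segments(m, "x", params).segments
        pos = m.sites["pos_bp"].to_numpy()
        rebuilt = np.full(len(codes), CODE_NA, dtype=np.int8)
        for s in segs1:
            rebuilt[(pos >= s.start_bp) & (pos < s.end_bp)] = s.genotype
        segs2 = call_segments(one_ind_matrix(rebuilt), "x", params).segments
        assert [(s.genotype,) for s in segs1] == [(s.genotype,) for s in segs2]

    def test_segmentation_idempotent_with_smoothing_on_long_segments(self):
        codes = [CODE_AA] * 40 + [CODE_AB] * 25 + [CODE_BB] * 35
        m = one_ind_matrix(codes)
        segs1 = call_segments(m, "x").segments
        pos = m.sites["pos_bp"].to_numpy()
        rebuilt = np.full(len(codes), CODE_NA, dtype=np.int8)
        for s in segs1:
            rebuilt[(pos >= s.start_bp) & (pos < s.end_bp)] = s.genotype
        segs2 = call_segments(one_ind_matrix(rebuilt), "x").segments
        assert [(s.genotype, s.start_bp, s.end_bp) for s in segs1] == \
               [(s.genotype, s.start_bp, s.end_bp) for s in segs2]

    def test_smooth_calls_ties_keep_original(self):
        # window of 4 non-missing around center: 2 AA vs 2 BB -> tie at edges
        obs = np.array([0, 0, 2, 2], dtype=np.int8)
        out = smooth_calls(obs, 5)
        assert np.array_equal(out, obs)


class TestRecombinationCounts:
    def test_single_segments_count_zero(self):
        s = SegmentSet("x", [Segment("chr1", 0, 10, 0, 5),
                             Segment("chr2", 0, 10, 1, 5)])
        assert count_recombination_events(s) == 0

    def test_multi_segment_chromosome_counts_transitions(self):
        s = SegmentSet("x", [Segment("chr1", 0, 10, 0, 5),
                             Segment("chr1", 10, 20, 1, 5),
                             Segment("chr1", 20, 30, 0, 5),
                             Segment("chr2", 0, 30, 2, 5)])
        assert count_recombination_events(s) == 2

    def test_expected_count_is_twice_map_morgans(self):
        assert expected_recombination_count(GeneticMap.uniform([0.0])) == 0.0
        assert expected_recombination_count(GeneticMap.uniform([100.0] * 10)) == 20.0

    def test_error_free_counts_match_truth_and_expectation(self, small_truth):
        """Clean data: segment counts equal truth; mean near 2L Morgans."""
        matrix = small_truth.true_matrix()
        counts = []
        for ind in matrix.individuals[:80]:
            segs = call_segments(matrix, ind, SegmentParams(1, 1))
            c = count_recombination_events(segs)
            assert c == small_truth.true_transition_count(ind)
            counts.append(c)
        expected = expected_recombination_count(small_truth.config.genetic_map)
        se = np.sqrt(expected / len(counts))  # Poisson-ish spread
        assert abs(np.mean(counts) - expected) < 4 * se


class TestFilterIndividuals:
    def _segsets(self, counts):
        out = []
        for i, c in enumerate(counts):
            segs = [Segment("chr1", k * 10, (k + 1) * 10, k % 2, 5)
                    for k in range(c + 1)]
            out.append(SegmentSet(f"i{i}", segs))
        return out

    def test_counts_at_expectation_keep_everyone(self):
        retained, report = filter_individuals(self._segsets([4, 4, 4]), 4.0, 2.0)
        assert len(retained) == 3 and not report["dropped"].any()

    def test_outlier_dropped(self):
        retained, report = filter_individuals(self._segsets([4, 40]), 4.0, 2.0)
        assert retained == ["i0"]
        assert report.loc[report["individual"] == "i1", "dropped"].item()

    def test_multiplier_must_exceed_one(self):
        with pytest.raises(ValueError):
            filter_individuals(self._segsets([1]), 4.0, 1.0)

    def test_error_inflated_individuals_dropped_more_often(self, two_chrom_map):
        cfg = simdata.SimConfig(genetic_map=two_chrom_map, qtls=(),
                                n_embryos=80, n_select_per_class=5,
                                snp_density=5.0, seed=21)
        truth = simdata.simulate_f2(cfg)
        rng = np.random.default_rng(0)
        clean = simdata.degrade_to_gbs(truth, rng=rng)
        noisy = simdata.degrade_to_gbs(truth, genotype_error_rate=0.10, rng=rng)
        expected = expected_recombination_count(two_chrom_map)
        _, rep_clean = filter_individuals(
            call_segments_all(clean, QC_SEGMENT_PARAMS), expected)
        _, rep_noisy = filter_individuals(
            call_segments_all(noisy, QC_SEGMENT_PARAMS), expected)
        assert rep_noisy["dropped"].mean() > rep_clean["dropped"].mean()


class TestHarmonizeBins:
    def test_identical_segmentation_returns_shared_segments(self):
        segs = [Segment("chr1", 0, 50_000, CODE_AA, 10),
                Segment("chr1", 50_000, 100_000, CODE_BB, 10)]
        s1 = SegmentSet("a", list(segs))
        s2 = SegmentSet("b", [Segment("chr1", 0, 50_000, CODE_BB, 10),
                              Segment("chr1", 50_000, 100_000, CODE_AA, 10)])
        gmap = GeneticMap.uniform([0.1], bp_per_cm=1e6)
        bins = harmonize_bins([s1, s2], gmap)
        assert bins.n_bins == 2
        assert bins.bins["start_bp"].tolist() == [0, 50_000]

    def test_offset_boundary_leaves_distinguishing_middle_bin(self):
        # same transition, offset by 20 kb: only the middle bin is
        # polymorphic and it separates the two individuals
        s1 = SegmentSet("a", [Segment("chr1", 0, 40_000, CODE_AA, 10),
                              Segment("chr1", 40_000, 100_000, CODE_BB, 10)])
        s2 = SegmentSet("b", [Segment("chr1", 0, 60_000, CODE_AA, 10),
                              Segment("chr1", 60_000, 100_000, CODE_BB, 10)])
        gmap = GeneticMap.uniform([0.1], bp_per_cm=1e6)
        bins = harmonize_bins([s1, s2], gmap)
        assert bins.n_bins == 1
        assert bins.bins.loc[0, ["start_bp", "end_bp"]].tolist() == [40_000, 60_000]
        assert bins.calls[0].tolist() == [CODE_BB, CODE_AA]

    def test_requires_two_individuals(self):
        s = SegmentSet("a", [Segment("chr1", 0, 10, CODE_AA, 3)])
        with pytest.raises(ValueError):
            harmonize_bins([s], GeneticMap.uniform([1.0]))

    def test_bin_calls_agree_with_segment_genotypes(self, small_truth):
        matrix = small_truth.true_matrix(small_truth.individuals[:30])
        segsets = call_segments_all(matrix, SegmentParams(1, 1))
        bins = harmonize_bins(segsets, small_truth.config.genetic_map)
        by_ind = {s.individual: s for s in segsets}
        rows = bins.bins.sample(40, random_state=0)
        for r, row in rows.iterrows():
            mid = (row["start_bp"] + row["end_bp"]) // 2
            for j, ind in enumerate(bins.individuals[:10]):
                expect = by_ind[ind].genotype_at(row["chrom"], mid)
                assert bins.calls[r, j] == expect

    def test_true_crossovers_lie_on_bin_boundaries(self, small_truth):
        matrix = small_truth.true_matrix(small_truth.individuals[:40])
        segsets = call_segments_all(matrix, SegmentParams(1, 1))
        bins = harmonize_bins(segsets, small_truth.config.genetic_map)
        edges = {
            (c, e)
            for c, s, e in zip(bins.bins["chrom"], bins.bins["start_bp"],
                               bins.bins["end_bp"])
            for e in (s, e)
        }
        for s in segsets:
            for seg_a, seg_b in zip(s.segments, s.segments[1:]):
                if seg_a.chrom == seg_b.chrom:
                    assert (seg_a.chrom, seg_a.end_bp) in edges
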