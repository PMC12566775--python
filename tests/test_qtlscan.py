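"""Logistic marker scan, EM interval mapping, peaks, joint fits."""

import numpy as np
import pandas as pd
import pytest

from callusmap import qtlscan
from callusmap.core import CODE_NA, GeneticMap, ScanResult
from callusmap.qtlscan import (
    align_phenotype,
    fdr_significant,
    find_peaks,
    genome_scan_logistic,
    genotype_class_summary,
    interval_scan_binary,
    lod_support_interval,
    logistic_marker_test,
    permutation_threshold,
    variance_explained,
)

from conftest import make_bins

LN10 = np.log(10)


def random_marker(rng, n=118, assoc=0.0):
    g = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25]).astype(np.int8)
    logit = assoc * (1 - g)  # dosage-coded effect
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
    return g, y


class TestLogisticMarkerTest:
    @pytest.mark.parametrize("assoc", [0.0, 1.0])
    def test_factor_lrt_matches_statsmodels_glm(self, rng, assoc):
        """Closed-form class-mean deviance equals an iterative GLM LRT."""
        import statsmodels.api as sm

        for _ in range(5):
            g, y = random_marker(rng, assoc=assoc)
            res = logistic_marker_test(g, y, coding="factor2df")
            X = pd.get_dummies(pd.Categorical(g), drop_first=True, dtype=float)
            X = sm.add_constant(X.to_numpy())
            full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, np.ones((y.size, 1)),
                          family=sm.families.Binomial()).fit()
            lrt_sm = 2 * (full.llf - null.llf)
            assert res.lrt == pytest.approx(lrt_sm, abs=1e-6)

    def test_additive_coding_uses_one_df(self, rng):
        g, y = random_marker(rng, assoc=1.0)
        res = logistic_marker_test(g, y, coding="additive1df")
        assert res.df == 1
        assert 0 < res.pvalue < 1

    def test_perfect_separation_is_tiny_p_with_ridge(self):
        g = np.array([0] * 59 + [2] * 59, dtype=np.int8)
        y = np.array([0] * 59 + [1] * 59, dtype=np.int8)
        res = logistic_marker_test(g, y)
        assert res.pvalue < 1e-6
        assert res.ridge_active
        assert all(np.isfinite(v) for v in res.coefficients.values())

    def test_monomorphic_marker_returns_missing(self):
        g = np.zeros(50, dtype=np.int8)
        y = np.array([0, 1] * 25, dtype=np.int8)
        res = logistic_marker_test(g, y)
        assert res.is_missing and res.reason == "monomorphic"

    def test_missing_calls_excluded_pairwise(self, rng):
        g, y = random_marker(rng)
        g2 = g.copy()
        g2[:10] = CODE_NA
        res = logistic_marker_test(g2, y)
        res_ref = logistic_marker_test(g[10:], y[10:])
        assert res.pvalue == pytest.approx(res_ref.pvalue)
        assert res.n == y.size - 10

    def test_lod_invariant_to_relabeling(self, rng):
        g, y = random_marker(rng, assoc=0.8)
        perm = rng.permutation(g.size)
        r1 = logistic_marker_test(g, y)
        r2 = logistic_marker_test(g[perm], y[perm])
        assert r1.lrt == pytest.approx(r2.lrt, abs=1e-9)


class TestGenomeScan:
    def test_single_bin_scan(self, rng):
        g, y = random_marker(rng, n=60)
        bins = make_bins(g[None, :], [10.0])
        scan = genome_scan_logistic(bins, y)
        assert len(scan.table) == 1
        assert scan.statistic_kind == "pvalue"

    def test_adding_monomorphic_marker_leaves_track_unchanged(self, rng):
        g, y = random_marker(rng, n=80, assoc=1.0)
        bins1 = make_bins(g[None, :], [10.0])
        calls2 = np.vstack([g, np.zeros_like(g)])
        bins2 = make_bins(calls2, [10.0, 20.0])
        s1 = genome_scan_logistic(bins1, y)
        s2 = genome_scan_logistic(bins2, y)
        assert s2.table["statistic"].iloc[0] == pytest.approx(
            s1.table["statistic"].iloc[0])
        assert np.isnan(s2.table["statistic"].iloc[1])

    def test_fdr_bh_hand_case(self):
        table = pd.DataFrame(
            {"chrom": "chr1", "pos_bp": [1, 2, 3], "pos_cm": [0.0, 1.0, 2.0],
             "statistic": [1e-8, 0.5, 0.9]})
        scan = ScanResult(table, "pvalue")
        hits = fdr_significant(scan, q=0.01)
        assert hits["pos_bp"].tolist() == [1]

    def test_fdr_all_ones_empty(self):
        table = pd.DataFrame({"chrom": "chr1", "pos_bp": [1, 2],
                              "pos_cm": [0.0, 1.0], "statistic": [1.0, 1.0]})
        assert fdr_significant(ScanResult(table, "pvalue")).empty


class TestPermutationThreshold:
    def test_same_seed_gives_identical_threshold(self, rng):
        calls = rng.choice([0, 1, 2], size=(20, 60)).astype(np.int8)
        bins = make_bins(calls, np.linspace(1, 99, 20))
        y = np.array([0, 1] * 30, dtype=np.int8)
        fn = qtlscan.logistic_extremum_fn(bins)
        t1, _ = permutation_threshold(fn, y, n_perm=100, alpha=0.05, rng=7)
        t2, _ = permutation_threshold(fn, y, n_perm=100, alpha=0.05, rng=7)
        assert t1 == t2

    def test_alpha_one_is_degenerate_max_quantile(self, rng):
        calls = rng.choice([0, 1, 2], size=(10, 40)).astype(np.int8)
        bins = make_bins(calls, np.linspace(1, 99, 10))
        y = np.array([0, 1] * 20, dtype=np.int8)
        fn = qtlscan.logistic_extremum_fn(bins)
        thr, extrema = permutation_threshold(fn, y, n_perm=50, alpha=1.0, rng=3)
        assert thr == extrema.max()


class TestIntervalScan:
    def test_constant_phenotype_gives_zero_lod(self, rng):
        calls = rng.choice([0, 1, 2], size=(8, 30)).astype(np.int8)
        bins = make_bins(calls, np.linspace(5, 95, 8))
        gmap = GeneticMap.uniform([100.0])
        y = np.ones(30, dtype=np.int8)
        scan = interval_scan_binary(bins, gmap, y, step_cm=5.0)
        assert np.allclose(scan.table["statistic"], 0.0, atol=1e-9)

    def test_lod_at_informative_marker_equals_single_marker_lrt(self, rng):
        """Complete data: EM collapses to the 2-df class-mean fit."""
        for _ in range(5):
            m, n = 10, 70
            pos = np.sort(rng.uniform(1, 99, m))
            calls = rng.choice([0, 1, 2], size=(m, n)).astype(np.int8)
            y = rng.integers(0, 2, n).astype(np.int8)
            if y.min() == y.max():
                continue
            bins = make_bins(calls, pos)
            gmap = GeneticMap.uniform([100.0])
            scan = interval_scan_binary(bins, gmap, y, step_cm=0)
            _, lrt = qtlscan._factor_scan(calls, y[None, :])
            grid_cm = scan.table["pos_cm"].to_numpy()
            for k, p in enumerate(pos):
                i = int(np.argmin(np.abs(grid_cm - p)))
                assert scan.table["statistic"].iloc[i] == pytest.approx(
                    lrt[0, k] / (2 * LN10), abs=1e-6)

    def test_missing_flank_scores_from_single_side(self):
        # individual 0 is only genotyped at 10 cM; positions near 90 cM are
        # scored from that single distant flank and relax toward the prior
        calls = np.array([[0, 2, 0, 2], [CODE_NA, 2, 0, 2]], dtype=np.int8)
        bins = make_bins(calls, [10.0, 90.0])
        gmap = GeneticMap.uniform([100.0])
        grid, W = qtlscan.compute_genotype_probs(bins, gmap, step_cm=10.0)
        assert np.allclose(W.sum(axis=2), 1.0)
        near = int(np.argmin(np.abs(grid["pos_cm"] - 10.0)))
        far = int(np.argmin(np.abs(grid["pos_cm"] - 90.0)))
        assert W[near, 0, 0] > 0.99  # at the marker: point mass on AA
        assert W[far, 0, 1] > 0.4  # 80 cM away: close to the 1:2:1 prior


class TestPeaksAndIntervals:
    def _lod_scan(self, lods, pos_cm=None, chrom="chr1"):
        pos_cm = np.arange(len(lods), dtype=float) if pos_cm is None else pos_cm
        return ScanResult(
            pd.DataFrame({"chrom": chrom, "pos_bp": (pos_cm * 1e6).astype(int),
                          "pos_cm": pos_cm, "statistic": lods}), "lod")

    def test_flat_scan_below_threshold_has_no_peaks(self):
        assert find_peaks(self._lod_scan([1.0] * 50), 3.0) == []

    def test_two_distant_bumps_give_two_peaks(self):
        lods = np.ones(150)
        lods[20:30] = 5.0
        lods[120:130] = 4.0
        peaks = find_peaks(self._lod_scan(lods), 3.0, min_separation_cm=30)
        assert len(peaks) == 2
        assert [p.peak_pos_cm for p in peaks] == [20.0, 120.0]

    def test_nearby_bumps_merge_keeping_stronger(self):
        lods = np.ones(60)
        lods[10:15] = 4.0
        lods[25:30] = 6.0
        peaks = find_peaks(self._lod_scan(lods), 3.0, min_separation_cm=30)
        assert len(peaks) == 1 and peaks[0].lod == 6.0

    def test_plateau_reports_leftmost_position(self):
        lods = np.zeros(50)
        lods[20:31] = 4.0
        peaks = find_peaks(self._lod_scan(lods), 3.0)
        assert peaks[0].peak_pos_cm == 20.0

    def test_support_interval_first_crossings(self):
        pos = np.arange(101, dtype=float)
        lods = 6.9 - np.abs(pos - 50) * 0.3  # symmetric tent around 50
        scan = self._lod_scan(lods, pos)
        peak = find_peaks(scan, 3.0)[0]
        lo, hi = lod_support_interval(scan, peak, drop=1.5)
        assert lo == 45e6 and hi == 55e6  # 1.5/0.3 = 5 cM each side

    def test_zero_drop_degenerates_to_peak_plateau(self):
        lods = np.zeros(30)
        lods[10:13] = 4.0
        scan = self._lod_scan(lods)
        peak = find_peaks(scan, 3.0)[0]
        lo, hi = lod_support_interval(scan, peak, drop=0.0)
        assert (lo, hi) == (10e6, 12e6)


class TestVarianceExplained:
    def test_closed_forms(self):
        assert variance_explained(0.0, 118) == 0.0
        assert variance_explained(59.0, 118) == pytest.approx(90.0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            variance_explained(1.0, 0)
        with pytest.raises(ValueError):
            variance_explained(-1.0, 10)


class TestGenotypeClassSummary:
    def _calls(self, n_aa, n_ab, n_bb, k_aa, k_ab, k_bb):
        g = np.array([0] * n_aa + [1] * n_ab + [2] * n_bb, dtype=np.int8)
        y = np.array(
            [1] * k_aa + [0] * (n_aa - k_aa)
            + [1] * k_ab + [0] * (n_ab - k_ab)
            + [1] * k_bb + [0] * (n_bb - k_bb), dtype=np.int8)
        return g, y

    def test_midway_heterozygote_is_additive(self):
        g, y = self._calls(20, 40, 20, 2, 20, 18)  # 0.1 / 0.5 / 0.9
        s = genotype_class_summary(g, y)
        assert s.dominance_call == "additive"
        assert s.favorable_allele == "B73"

    def test_heterozygote_at_homozygote_level_is_dominant(self):
        g, y = self._calls(20, 40, 20, 18, 36, 2)  # 0.9 / 0.9 / 0.1
        s = genotype_class_summary(g, y)
        assert s.dominance_call == "dominant"
        assert s.favorable_allele == "A188"

    def test_overdominant_heterozygote_is_partial(self):
        g, y = self._calls(20, 40, 20, 8, 39, 12)  # 0.4 / 0.975 / 0.6
        s = genotype_class_summary(g, y)
        assert s.dominance_call == "partial"

    def test_empty_genotype_class_withholds_call(self):
        g, y = self._calls(20, 0, 20, 2, 0, 18)
        s = genotype_class_summary(g, y)
        assert s.dominance_call is None
        assert np.isnan(s.type2_proportion["AB"])

    def test_counts_sum_to_class_sizes(self):
        g, y = self._calls(10, 20, 10, 5, 10, 5)
        s = genotype_class_summary(g, y)
        assert s.counts.to_numpy().sum() == 40
        assert s.counts.loc["TypeII"].sum() == int(y.sum())


class TestPowerMonotonicity:
    def test_power_increases_with_effect_size(self):
        """Detection rate grows along a 3-point |beta| grid at fixed n."""
        rng = np.random.default_rng(2024)
        n, reps = 150, 300
        power = []
        for beta in (0.0, 0.6, 1.2):
            hits = 0
            for _ in range(reps):
                g = rng.choice([0, 1, 2], size=n, p=[0.25, 0.5, 0.25])
                logit = beta * (g - 1)
                y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(np.int8)
                if y.min() == y.max():
                    continue
                pv, _ = qtlscan._factor_scan(g[None, :].astype(np.int8),
                                             y[None, :])
                hits += pv[0, 0] < 0.05
            power.append(hits / reps)
        assert power[0] < power[1] < power[2]
        assert power[0] < 0.10  # near-nominal under the null


class TestAlignPhenotype:
    def test_label_and_integer_coding(self):
        y = align_phenotype(["a", "b", "c"],
                            {"a": "TypeI", "b": "TypeII", "c": 0})
        assert y.tolist() == [0, 1, 0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            align_phenotype(["a", "b"], {"a": 1, "b": 1})

    def test_missing_individual_rejected(self):
        with pytest.raises(KeyError):
            align_phenotype(["a", "b"], {"a": 1})
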