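"""Generative-model checks: meiosis, liability phenotype, GBS noise, bulks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from callusmap import simdata
from callusmap.core import CODE_AA, CODE_NA, GeneticMap
from callusmap.simdata import QtlSpec, SimConfig


def _dummy_truth(dosage: np.ndarray, seed: int = 0) -> simdata.F2Truth:
    """Wrap a fixed dosage matrix in an F2Truth for degradation/bulk tests."""
    n_snps, n_ind = dosage.shape
    gmap = GeneticMap.uniform([float(n_snps)])
    cfg = SimConfig(genetic_map=gmap, qtls=(), n_embryos=max(n_ind, 2),
                    n_select_per_class=1, seed=seed)
    sites = pd.DataFrame(
        {"chrom": "chr1", "pos_bp": np.arange(n_snps) * 1000,
         "pos_cm": np.arange(n_snps, dtype=float)}
    )
    inds = [f"I{j}" for j in range(n_ind)]
    return simdata.F2Truth(
        config=cfg, snp_sites=sites, individuals=inds, gametes=[],
        dosage=dosage.astype(np.int8), qtl_dosage=np.zeros((0, n_ind), np.int8),
        liability=np.zeros(n_ind), phenotype=np.zeros(n_ind, np.int8),
    )


class TestMeiosis:
    def test_zero_length_chromosome_yields_no_crossovers(self, rng):
        gmap = GeneticMap.uniform([0.0])
        for _ in range(20):
            g = simdata.simulate_gamete(gmap, rng)
            assert g.breaks[0].size == 0

    def test_crossover_count_matches_poisson_mean(self, rng):
        gmap = GeneticMap.uniform([100.0])
        counts = [simdata.simulate_gamete(gmap, rng).breaks[0].size
                  for _ in range(10_000)]
        se = np.sqrt(1.0 / 10_000)  # Poisson(1) mean variance
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_crossover_count_poisson_gof(self, rng):
        gmap = GeneticMap.uniform([150.0])
        counts = np.array([simdata.simulate_gamete(gmap, rng).breaks[0].size
                           for _ in range(10_000)])
        kmax = 6
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), 1.5)
        expected = np.append(pmf, 1 - pmf.sum()) * counts.size
        _, p = stats.chisquare(obs, expected)
        assert p > 0.01

    def test_recombination_fraction_matches_haldane(self, rng):
        gmap = GeneticMap.uniform([60.0])
        n = 20_000
        recomb = 0
        for _ in range(n):
            g = simdata.simulate_gamete(gmap, rng)
            a, b = g.allele(0, 5.0), g.allele(0, 55.0)
            recomb += int(a != b)
        expected = 0.5 * (1 - np.exp(-2 * 50 / 100))  # ~0.316
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(recomb / n - expected) < 3 * se

    def test_founder_phase_is_balanced(self, rng):
        gmap = GeneticMap.uniform([50.0])
        phases = [simdata.simulate_gamete(gmap, rng).phases[0] for _ in range(5000)]
        assert abs(np.mean(phases) - 0.5) < 3 * np.sqrt(0.25 / 5000)


class TestF2Simulation:
    def test_null_model_gives_balanced_phenotype(self):
        cfg = SimConfig(genetic_map=GeneticMap.uniform([100.0]), qtls=(), mu=0.0,
                        n_embryos=4000, n_select_per_class=10, seed=5)
        truth = simdata.simulate_f2(cfg)
        se = np.sqrt(0.25 / 4000)
        assert abs(truth.phenotype.mean() - 0.5) < 3 * se

    def test_single_qtl_penetrance_matches_logistic(self):
        cfg = SimConfig(genetic_map=GeneticMap.uniform([100.0]),
                        qtls=(QtlSpec("chr1", 50.0, 2.0),), mu=0.0,
                        n_embryos=6000, n_select_per_class=10, seed=6)
        truth = simdata.simulate_f2(cfg)
        aa = truth.qtl_dosage[0] == 2  # A188 homozygotes
        p_hat = truth.phenotype[aa].mean()
        expected = 1 / (1 + np.exp(-2.0))  # ~0.881
        se = np.sqrt(expected * (1 - expected) / aa.sum())
        assert abs(p_hat - expected) < 3 * se

    def test_genotype_frequencies_fit_1_2_1(self):
        cfg = SimConfig(genetic_map=GeneticMap.uniform([100.0]), qtls=(),
                        n_embryos=3000, n_select_per_class=10, snp_density=0.5,
                        seed=7)
        truth = simdata.simulate_f2(cfg)
        for row in truth.dosage[::10]:
            obs = np.bincount(row, minlength=3)
            _, p = stats.chisquare(obs, np.array([0.25, 0.5, 0.25]) * row.size)
            assert p > 1e-5  # no marker wildly off 1:2:1

    def test_five_qtl_architecture_enriches_a188_on_chr6_in_type2(self):
        truth = simdata.simulate_f2(simdata.default_config(seed=3))
        qi = [q.chrom for q in truth.config.qtls].index("chr6")
        i1 = [truth.individuals.index(i) for i in truth.selected_type1]
        i2 = [truth.individuals.index(i) for i in truth.selected_type2]
        # chr6 beta > 0: A188 dosage higher among Type II extremes
        assert truth.qtl_dosage[qi, i2].mean() > truth.qtl_dosage[qi, i1].mean()

    def test_selection_failure_reports_class_sizes(self):
        cfg = SimConfig(genetic_map=GeneticMap.uniform([50.0]), qtls=(),
                        mu=5.0, n_embryos=100, n_select_per_class=40, seed=8)
        with pytest.raises(ValueError, match="Type I ="):
            simdata.simulate_f2(cfg)

    def test_same_seed_is_bit_reproducible(self):
        cfg = simdata.default_config(seed=42, n_embryos=200, n_select_per_class=20)
        t1, t2 = simdata.simulate_f2(cfg), simdata.simulate_f2(cfg)
        assert np.array_equal(t1.dosage, t2.dosage)
        assert t1.selected_type1 == t2.selected_type1
        assert np.array_equal(t1.liability, t2.liability)


class TestGbsDegradation:
    def test_zero_rates_is_identity(self, rng):
        dosage = rng.integers(0, 3, size=(100, 20)).astype(np.int8)
        truth = _dummy_truth(dosage)
        out = simdata.degrade_to_gbs(truth, missing_rate=0, genotype_error_rate=0,
                                     het_undercall_rate=0, rng=rng)
        assert np.array_equal(out.calls, truth.genotype_codes)

    def test_missing_rate_one_blanks_everything(self, rng):
        truth = _dummy_truth(np.ones((50, 10), np.int8))
        out = simdata.degrade_to_gbs(truth, missing_rate=1, genotype_error_rate=0,
                                     het_undercall_rate=0, rng=rng)
        assert (out.calls == CODE_NA).all()

    def test_error_rate_corrupts_binomially(self, rng):
        truth = _dummy_truth(np.full((500, 20), 2, np.int8))  # all AA
        out = simdata.degrade_to_gbs(truth, missing_rate=0, genotype_error_rate=0.02,
                                     het_undercall_rate=0, rng=rng)
        n_bad = int((out.calls != CODE_AA).sum())
        se = np.sqrt(10_000 * 0.02 * 0.98)
        assert abs(n_bad - 200) < 3 * se

    def test_het_undercall_only_hits_heterozygotes(self, rng):
        dosage = np.where(np.arange(200)[:, None] % 2 == 0, 1, 2).astype(np.int8)
        truth = _dummy_truth(dosage)
        out = simdata.degrade_to_gbs(truth, missing_rate=0, genotype_error_rate=0,
                                     het_undercall_rate=0.5, rng=rng)
        hom_rows = out.calls[1::2]  # true AA rows untouched
        assert np.array_equal(hom_rows, truth.genotype_codes[1::2])
        het_rows = out.calls[0::2]
        frac_undercalled = (het_rows != 1).mean()
        assert 0.4 < frac_undercalled < 0.6


class TestBulkCounts:
    def test_pure_a188_bulk_has_only_a188_reads(self, rng):
        truth = _dummy_truth(np.full((100, 8), 2, np.int8))
        counts = simdata.simulate_bulk_counts(
            truth, bulks={"b1": ("XT-I", truth.individuals[:4])},
            depth_mean=100, rng=rng)
        assert (counts["b73_reads"] == 0).all()
        assert counts["a188_reads"].sum() > 0

    def test_half_frequency_bulk_read_fraction(self, rng):
        truth = _dummy_truth(np.ones((5000, 10), np.int8))  # all het -> f=0.5
        counts = simdata.simulate_bulk_counts(
            truth, bulks={"b1": ("XT-I", truth.individuals)}, depth_mean=200,
            rng=rng)
        frac = counts["a188_reads"].sum() / (
            counts["a188_reads"].sum() + counts["b73_reads"].sum())
        se = 0.5 / np.sqrt(5000 * 200)
        assert abs(frac - 0.5) < 4 * se

    def test_empty_bulk_rejected(self, rng):
        truth = _dummy_truth(np.ones((10, 4), np.int8))
        with pytest.raises(ValueError, match="empty"):
            simdata.simulate_bulk_counts(truth, bulks={"b": ("XT-I", [])}, rng=rng)

    def test_qtl_linked_snp_diverges_between_class_bulks(self):
        """Allele-frequency gap at the QTL exceeds unlinked background."""
        gmap = GeneticMap.uniform([100.0, 100.0])
        cfg = SimConfig(genetic_map=gmap, qtls=(QtlSpec("chr1", 50.0, 1.5),),
                        n_embryos=600, n_select_per_class=50, snp_density=0.5,
                        bulk_size=25, seed=11)
        truth = simdata.simulate_f2(cfg)
        counts = simdata.simulate_bulk_counts(truth)
        pooled = counts.groupby(["chrom", "pos_bp", "phenotype_class"])[
            ["a188_reads", "b73_reads"]].sum().reset_index()
        piv = pooled.pivot_table(index=["chrom", "pos_bp"],
                                 columns="phenotype_class", values="a188_reads")
        tot = pooled.pivot_table(index=["chrom", "pos_bp"],
                                 columns="phenotype_class",
                                 values=["a188_reads", "b73_reads"],
                                 aggfunc="sum")
        depth = tot["a188_reads"] + tot["b73_reads"]
        gap = (piv / depth)["XT-II"] - (piv / depth)["XT-I"]
        gap = gap.reset_index()
        near = gap[(gap["chrom"] == "chr1") & (abs(gap["pos_bp"] - 50e6) < 5e6)]
        far = gap[gap["chrom"] == "chr2"]
        assert abs(near.iloc[:, -1]).mean() > abs(far.iloc[:, -1]).mean()


class TestGeneFixture:
    def test_zero_genes_gives_empty_tables(self, rng):
        genes, d1, d2 = simdata.make_gene_fixture(GeneticMap.uniform([50.0]), 0,
                                                  rng=rng)
        assert genes.empty and d1.empty and d2.empty

    def test_deg_lists_reference_existing_genes(self, rng):
        gmap = GeneticMap.uniform([100.0, 80.0])
        genes, d1, d2 = simdata.make_gene_fixture(gmap, 200, rng=rng)
        assert set(d1["gene_id"]).issubset(set(genes["gene_id"]))
        assert set(d2["gene_id"]).issubset(set(genes["gene_id"]))
        assert set(d1["direction"]).issubset({"up", "down"})
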