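"""Study-level validation experiments on synthetic data.

Each function builds its own synthetic inputs at a stated scale, runs the
relevant pipeline stages end to end, and returns summary statistics.  They
back the package's self-validation suite and the reproduction script, and
are equally usable interactively (see ``examples/``).

Problem sizes are chosen for desk-scale runtimes: the genome used for the
full-design experiments is the ten-chromosome maize-shaped default map, the
scan-calibration experiment uses a deliberately small two-chromosome genome
so that hundreds of null datasets with full permutation thresholds stay
cheap, and the BSR calibration uses closed-form vectorized tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import binmarkers, bsrseq, qtlscan, simdata
from .binmarkers import QC_SEGMENT_PARAMS, SegmentParams
from .core import BinMarkerMatrix, GeneticMap

__all__ = [
    "bins_from_genotype_matrix",
    "segmentation_exact_recovery",
    "recombination_qc_contrast",
    "scan_calibration",
    "complete_data_equivalence",
    "five_qtl_recovery",
    "bsr_chi2_agreement",
    "bsr_familywise_error",
]


def bins_from_genotype_matrix(
    matrix, genetic_map: GeneticMap
) -> BinMarkerMatrix:
    """Treat each SNP as its own bin marker (no segmentation)."""
    pos_bp = matrix.sites["pos_bp"].to_numpy(np.int64)
    pos_cm = np.concatenate(
        [
            np.asarray(genetic_map.chromosome(chrom).bp_to_cm(pos_bp[sl]), float)
            for chrom, sl in matrix.chrom_slices().items()
        ]
    )
    bins = pd.DataFrame(
        {
            "chrom": matrix.sites["chrom"],
            "start_bp": pos_bp,
            "end_bp": pos_bp + 1,
            "rep_pos_bp": pos_bp,
            "rep_pos_cm": pos_cm,
        }
    )
    return BinMarkerMatrix(bins, list(matrix.individuals), matrix.calls.copy())


def _validation_map() -> GeneticMap:
    return GeneticMap.uniform([120.0] * 10)


def segmentation_exact_recovery(seed: int, n: int = 200) -> dict:
    """Error-free F2 (10 x 120 cM, 5 SNPs/cM): does run-length segmentation
    reproduce the true crossover segmentation for every individual?

    Smoothing is off (window 1, min 1 SNP) — on clean dense data the
    segmenter should be exact; the default smoothing deliberately trades
    such exactness for noise robustness.
    """
    cfg = simdata.SimConfig(
        genetic_map=_validation_map(), qtls=(), n_embryos=n,
        n_select_per_class=1, snp_density=5.0, missing_rate=0.0,
        genotype_error_rate=0.0, het_undercall_rate=0.0, seed=seed,
    )
    truth = simdata.simulate_f2(cfg)
    matrix = truth.true_matrix()
    params = SegmentParams(1, 1)
    exact = 0
    for ind in matrix.individuals:
        segs = binmarkers.call_segments(matrix, ind, params)
        if (binmarkers.count_recombination_events(segs)
                == truth.true_transition_count(ind)):
            exact += 1
    return {"fraction_exact": exact / n, "n": n}


def recombination_qc_contrast(
    seed: int, n: int = 200, multiplier: float = 2.0
) -> dict:
    """Drop-rate contrast of the excess-recombination filter.

    The same individuals are degraded twice: at the default GBS noise and at
    5x the default genotype error rate.  The QC segmentation (light
    smoothing) feeds the filter at the given multiplier over the 2L-Morgan
    expectation.
    """
    gmap = _validation_map()
    cfg = simdata.SimConfig(
        genetic_map=gmap, qtls=(), n_embryos=n, n_select_per_class=1,
        snp_density=5.0, seed=seed,
    )
    truth = simdata.simulate_f2(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    clean = simdata.degrade_to_gbs(truth, rng=rng)
    noisy = simdata.degrade_to_gbs(
        truth, genotype_error_rate=5 * cfg.genotype_error_rate, rng=rng)
    expected = binmarkers.expected_recombination_count(gmap)
    rates = {}
    for label, matrix in (("clean", clean), ("noisy", noisy)):
        segsets = binmarkers.call_segments_all(matrix, QC_SEGMENT_PARAMS)
        _, report = binmarkers.filter_individuals(segsets, expected, multiplier)
        rates[label] = float(report["dropped"].mean())
    ratio = (rates["noisy"] / rates["clean"] if rates["clean"] > 0
             else float("inf") if rates["noisy"] > 0 else float("nan"))
    return {"clean_drop_rate": rates["clean"], "noisy_drop_rate": rates["noisy"],
            "rate_ratio": ratio, "n": n}


def scan_calibration(
    seed: int,
    n_datasets: int = 200,
    n_perm: int = 200,
    alpha: float = 0.05,
    n_individuals: int = 100,
) -> dict:
    """Genome-wide type-I error of both scans under the null.

    Each dataset is an F2 with no QTL on a small two-chromosome genome; its
    own permutation threshold (``n_perm`` shuffles) is computed and the
    fraction of datasets whose unpermuted genome-wide extremum beats it is
    returned — nominally ~alpha.
    """
    gmap = GeneticMap.uniform([60.0, 60.0])
    ss = np.random.SeedSequence([seed, 2])
    child_seeds = ss.generate_state(n_datasets * 2).reshape(n_datasets, 2)
    hits_logistic = 0
    hits_interval = 0
    used = 0
    for k in range(n_datasets):
        cfg = simdata.SimConfig(
            genetic_map=gmap, qtls=(), n_embryos=n_individuals,
            n_select_per_class=1, snp_density=0.5, missing_rate=0.0,
            genotype_error_rate=0.0, het_undercall_rate=0.0,
            seed=int(child_seeds[k, 0] % (2**31)),
        )
        truth = simdata.simulate_f2(cfg)
        y = truth.phenotype
        if y.min() == y.max():
            continue
        used += 1
        bins = bins_from_genotype_matrix(truth.true_matrix(), gmap)
        rng = np.random.default_rng(int(child_seeds[k, 1] % (2**31)))

        log_fn = qtlscan.logistic_extremum_fn(bins)
        thr_p, _ = qtlscan.permutation_threshold(
            log_fn, y, n_perm=n_perm, alpha=alpha, rng=rng)
        obs_p = float(log_fn(y[None, :])[0])
        hits_logistic += obs_p < thr_p

        int_fn = qtlscan.interval_extremum_fn(bins, gmap, step_cm=2.5)
        thr_l, _ = qtlscan.permutation_threshold(
            int_fn, y, n_perm=n_perm, alpha=alpha, rng=rng,
            higher_is_stronger=True)
        obs_l = float(int_fn(y[None, :])[0])
        hits_interval += obs_l > thr_l
    return {
        "logistic_fwer": hits_logistic / used,
        "interval_fwer": hits_interval / used,
        "n_datasets": used,
        "n_perm": n_perm,
        "alpha": alpha,
    }


def complete_data_equivalence(seed: int, n_fixtures: int = 50) -> dict:
    """Max |interval-mapping LOD - single-marker 2-df LOD| at fully
    informative marker positions over random fixtures."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    gmap = GeneticMap.uniform([100.0])
    worst = 0.0
    done = 0
    while done < n_fixtures:
        m = int(rng.integers(5, 15))
        n = int(rng.integers(40, 120))
        pos = np.sort(rng.uniform(1, 99, m))
        if np.min(np.diff(pos)) < 1e-3:
            continue
        calls = rng.choice([0, 1, 2], size=(m, n)).astype(np.int8)
        y = rng.integers(0, 2, n).astype(np.int8)
        if y.min() == y.max():
            continue
        bins = pd.DataFrame(
            {"chrom": "chr1", "start_bp": (pos * 1e6).astype(np.int64),
             "end_bp": (pos * 1e6).astype(np.int64) + 1,
             "rep_pos_bp": (pos * 1e6).astype(np.int64), "rep_pos_cm": pos})
        bmm = BinMarkerMatrix(bins, [f"i{j}" for j in range(n)], calls)
        scan = qtlscan.interval_scan_binary(bmm, gmap, y, step_cm=0)
        _, lrt = qtlscan._factor_scan(calls, y[None, :])
        lod_marker = lrt[0] / (2 * np.log(10))
        grid_cm = scan.table["pos_cm"].to_numpy()
        for k, p in enumerate(pos):
            i = int(np.argmin(np.abs(grid_cm - p)))
            worst = max(worst, abs(float(scan.table["statistic"].iloc[i])
                                   - float(lod_marker[k])))
        done += 1
    return {"max_abs_lod_diff": worst, "n_fixtures": n_fixtures}


def five_qtl_recovery(
    seed: int,
    n_reps: int = 20,
    lod_threshold: float = 3.0,
    window_cm: float = 15.0,
) -> dict:
    """Full-pipeline recovery of the five-QTL architecture.

    Per replicate: study-scale simulation (2194 embryos, 100+100 extremes,
    default GBS degradation with 2% error / 20% missing), QC filtering,
    bin-marker harmonization, EM interval scan, peak calling at the fixed
    LOD threshold, allele and dominance annotation, and a joint fit for the
    variance explained.  A QTL counts as detected when the strongest peak on
    its chromosome lies within ``window_cm`` of the true position.
    """
    gmap = simdata.default_map()
    qtls = simdata.five_qtl_architecture(gmap)
    truth_pos = {q.chrom: q.pos_cm for q in qtls}
    truth_fav = {q.chrom: ("A188" if q.beta > 0 else "B73") for q in qtls}
    ss = np.random.SeedSequence([seed, 4])
    rep_seeds = ss.generate_state(n_reps) % (2**31)

    n_detected = n_sign_ok = n_additive = 0
    varexp = []
    for rep in range(n_reps):
        cfg = simdata.SimConfig(genetic_map=gmap, qtls=tuple(qtls),
                                seed=int(rep_seeds[rep]))
        truth = simdata.simulate_f2(cfg)
        selected = truth.selected_type1 + truth.selected_type2
        gbs = simdata.degrade_to_gbs(truth, individuals=selected)
        qc_segs = binmarkers.call_segments_all(gbs, QC_SEGMENT_PARAMS)
        expected = binmarkers.expected_recombination_count(gmap)
        retained, _ = binmarkers.filter_individuals(qc_segs, expected, 2.0)
        segsets = binmarkers.call_segments_all(gbs.subset_individuals(retained))
        bins = binmarkers.harmonize_bins(segsets, gmap)
        pheno = {i: 0 for i in truth.selected_type1}
        pheno.update({i: 1 for i in truth.selected_type2})
        y = qtlscan.align_phenotype(bins.individuals, pheno)
        scan = qtlscan.interval_scan_binary(bins, gmap, y, step_cm=2.0)
        peaks = qtlscan.find_peaks(scan, lod_threshold)
        qtlscan.annotate_peaks(peaks, bins, y, scan=scan)
        best: dict[str, qtlscan.QtlPeak] = {}
        for p in peaks:
            if p.chrom not in best or p.lod > best[p.chrom].lod:
                best[p.chrom] = p
        if best:
            joint_lod, n_used = qtlscan.joint_qtl_fit(bins, list(best.values()), y)
            varexp.append(qtlscan.variance_explained(joint_lod, n_used))
        for chrom, true_cm in truth_pos.items():
            p = best.get(chrom)
            if p is None or abs(p.peak_pos_cm - true_cm) > window_cm:
                continue
            n_detected += 1
            n_sign_ok += p.favorable_allele == truth_fav[chrom]
            n_additive += p.dominance_call == "additive"
    n_total = n_reps * len(qtls)
    return {
        "detection_rate": n_detected / n_total,
        "sign_correct_rate": n_sign_ok / max(n_detected, 1),
        "additive_call_rate": n_additive / max(n_detected, 1),
        "mean_variance_explained_pct": float(np.mean(varexp)) if varexp else 0.0,
        "n_qtl_instances": n_total,
        "n_detected": n_detected,
    }


def bsr_chi2_agreement(seed: int, n_tables: int = 1000) -> dict:
    """Max |log10 p| gap between the binomial deviance test and a Pearson
    chi-square oracle over random 2x2 tables at depth >= 100."""
    from scipy import stats

    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    worst = 0.0
    done = 0
    while done < n_tables:
        f = rng.uniform(0.2, 0.8)
        delta = rng.uniform(-0.1, 0.1)
        d1, d2 = rng.poisson(200, 2) + 100
        a1 = rng.binomial(d1, np.clip(f, 0.01, 0.99))
        a2 = rng.binomial(d2, np.clip(f + delta, 0.01, 0.99))
        table = np.array([[a1, d1 - a1], [a2, d2 - a2]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        _, p_dev = bsrseq.binomial_deviance_test(a1, d1 - a1, a2, d2 - a2)
        _, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
        p_dev = max(float(p_dev), 1e-300)
        p_chi = max(float(p_chi), 1e-300)
        worst = max(worst, abs(np.log10(p_dev) - np.log10(p_chi)))
        done += 1
    return {"max_abs_log10_p_diff": worst, "n_tables": n_tables}


def bsr_familywise_error(
    seed: int, n_snps: int = 10_000, n_replicates: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Familywise error of the Bonferroni-thresholded scan on null genomes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    cutoff = bsrseq.bonferroni_cutoff(n_snps, alpha)
    fw_hits = 0
    for _ in range(n_replicates):
        f = rng.uniform(0.2, 0.8, size=n_snps)
        d1 = rng.poisson(200, n_snps) + 100
        d2 = rng.poisson(200, n_snps) + 100
        a1 = rng.binomial(d1, f)
        a2 = rng.binomial(d2, f)
        _, p = bsrseq.binomial_deviance_test(a1, d1 - a1, a2, d2 - a2)
        fw_hits += bool(np.nanmin(p) <= cutoff)
    return {"familywise_error": fw_hits / n_replicates,
            "n_replicates": n_replicates, "n_snps": n_snps, "alpha": alpha}
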