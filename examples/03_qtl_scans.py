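"""Map the callus-type phenotype with both genome scans.

Runs the 2-df logistic scan (FDR 1% + permutation threshold) and the
binary-model EM interval scan (permutation LOD threshold), calls peaks
with LOD support intervals, and fits all peaks jointly for the variance
explained.
"""

import numpy as np

from callusmap import binmarkers, qtlscan, simdata

cfg = simdata.default_config(seed=7)
truth = simdata.simulate_f2(cfg)
selected = truth.selected_type1 + truth.selected_type2
gbs = simdata.degrade_to_gbs(truth, individuals=selected)
qc = binmarkers.call_segments_all(gbs, binmarkers.QC_SEGMENT_PARAMS)
expected = binmarkers.expected_recombination_count(cfg.genetic_map)
retained, _ = binmarkers.filter_individuals(qc, expected, 2.0)
bins = binmarkers.harmonize_bins(
    binmarkers.call_segments_all(gbs.subset_individuals(retained)),
    cfg.genetic_map)
pheno = {i: 0 for i in truth.selected_type1}
pheno.update({i: 1 for i in truth.selected_type2})
y = qtlscan.align_phenotype(bins.individuals, pheno)
print(f"{bins.n_bins} bin markers, {y.size} individuals "
      f"({int(y.sum())} Type II)")

logistic = qtlscan.genome_scan_logistic(bins, y)
fdr_hits = qtlscan.fdr_significant(logistic, q=0.01)
thr_p, _ = qtlscan.permutation_threshold(
    qtlscan.logistic_extremum_fn(bins), y, n_perm=200, alpha=0.05, rng=0)
print(f"logistic scan: min p = {logistic.genome_extremum():.2e}, "
      f"{len(fdr_hits)} bins at FDR 1%, permutation cutoff {thr_p:.2e}")

scan = qtlscan.interval_scan_binary(bins, cfg.genetic_map, y, step_cm=2.0)
thr_lod, _ = qtlscan.permutation_threshold(
    qtlscan.interval_extremum_fn(bins, cfg.genetic_map), y,
    n_perm=200, alpha=0.05, rng=0, higher_is_stronger=True)
peaks = qtlscan.find_peaks(scan, max(thr_lod, 3.0))
qtlscan.annotate_peaks(peaks, bins, y, scan=scan)
print(f"interval scan: permutation LOD threshold {thr_lod:.2f}")
for p in sorted(peaks, key=lambda p: -p.lod):
    lo, hi = p.interval_bp
    print(f"  {p.chrom:5s} peak {p.peak_pos_cm:6.1f} cM  LOD {p.lod:5.1f}  "
          f"favorable={p.favorable_allele}  {p.dominance_call}  "
          f"interval {lo/1e6:.1f}-{hi/1e6:.1f} Mb")

best = {}
for p in peaks:
    if p.chrom not in best or p.lod > best[p.chrom].lod:
        best[p.chrom] = p
joint_lod, n_used = qtlscan.joint_qtl_fit(bins, list(best.values()), y)
print(f"joint fit of {len(best)} peaks (n={n_used}): "
      f"LOD {joint_lod:.1f} -> variance explained "
      f"{qtlscan.variance_explained(joint_lod, n_used):.1f}%")
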