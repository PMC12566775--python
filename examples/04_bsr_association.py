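"""Bulk-segregant RNA-seq allele association.

Simulates binomial allele read counts for two 50-callus bulks per
phenotype class, pools replicates, tests every SNP with the binomial
deviance (GLM) test, and thresholds with Bonferroni at 5%.
"""

import numpy as np

from callusmap import bsrseq, simdata

cfg = simdata.default_config(seed=3)
truth = simdata.simulate_f2(cfg)
counts = simdata.simulate_bulk_counts(truth)
n_snps = counts.groupby(["chrom", "pos_bp"]).ngroups
print(f"{n_snps} SNPs x {counts['bulk_id'].nunique()} bulks; "
      f"mean depth {(counts['a188_reads'] + counts['b73_reads']).mean():.0f}")

scan = bsrseq.bsr_scan(counts, alpha=0.05)
cutoff = bsrseq.bonferroni_cutoff(scan["pvalue"].notna().sum())
sig = scan[scan["significant"]]
print(f"Bonferroni cutoff: {cutoff:.2e}")
print(f"significant SNPs: {len(sig)}/{len(scan)}")

# significant SNPs should cluster on the QTL-bearing chromosomes
qtl_chroms = {q.chrom for q in cfg.qtls}
on_qtl = sig["chrom"].isin(qtl_chroms).mean()
print(f"fraction of significant SNPs on QTL chromosomes: {on_qtl:.2f} "
      f"({len(qtl_chroms)}/10 chromosomes carry a QTL)")
top = sig.sort_values("pvalue").head(5)
for _, r in top.iterrows():
    print(f"  {r['chrom']:5s} {r['pos_bp']/1e6:7.2f} Mb  p={r['pvalue']:.2e}  "
          f"A188-enriched in {r['a188_enriched_in']}")
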