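"""Inbred segment profiling and QTL x DEG candidate genes.

Profiles a nearly inbred line's chromosomal segments, looks up its alleles
at the QTL peaks, and intersects QTL support intervals with two directed
DEG lists to produce candidate genes.
"""

import numpy as np
import pandas as pd

from callusmap import integrate, simdata
from callusmap.binmarkers import SegmentParams
from callusmap.core import QtlPeak

rng = np.random.default_rng(42)
gmap = simdata.default_map()
qtls = simdata.five_qtl_architecture(gmap)

# QTL support intervals (+-12 cM around each true position, as a stand-in
# for scan output) and a random gene/DEG fixture enriched inside them
intervals = pd.DataFrame([
    {"qtl": f"ct{q.chrom[3:]}", "chrom": q.chrom,
     "start_bp": int(gmap.chromosome(q.chrom).cm_to_bp(q.pos_cm - 12)),
     "end_bp": int(gmap.chromosome(q.chrom).cm_to_bp(q.pos_cm + 12))}
    for q in qtls
])
genes, deg1, deg2 = simdata.make_gene_fixture(gmap, 2000, intervals, rng=rng)
cands = integrate.candidate_genes(intervals, genes, deg1, deg2)
print(f"{len(genes)} genes, {len(deg1)}/{len(deg2)} DEGs per contrast")
print(f"candidate genes in QTL intervals, concordant in both contrasts: "
      f"{len(cands)} ({(cands['direction'] == 'up').sum()} up / "
      f"{(cands['direction'] == 'down').sum()} down)")

# a synthetic nearly-inbred culturable line: B73 fixed on chr2/6/8 blocks
truth = simdata.simulate_f2(simdata.default_config(
    seed=2, n_embryos=50, n_select_per_class=5))
line = truth.individuals[0]
matrix = truth.true_matrix([line])
profile = integrate.profile_inbred(matrix, line, SegmentParams(1, 1))
print(f"line {line}: {profile.breakpoint_count} recombination breakpoints")

peaks = [QtlPeak(f"ct{q.chrom[3:]}", q.chrom,
                 int(gmap.chromosome(q.chrom).cm_to_bp(q.pos_cm)), q.pos_cm,
                 favorable_allele="A188" if q.beta > 0 else "B73")
         for q in qtls]
table = integrate.allele_at_qtl(profile, peaks)
print(table.to_string(index=False))

# z-score an RPM matrix for heatmap-style reporting
rpm = pd.DataFrame(rng.gamma(2.0, 20.0, size=(5, 4)),
                   columns=["XT-I_1", "XT-I_2", "XT-II_1", "XT-II_2"],
                   index=[f"gene{i}" for i in range(5)])
z, flags = integrate.standardize_expression(rpm)
print("standardized expression (rows: mean 0, sd 1):")
print(z.round(2).to_string())
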