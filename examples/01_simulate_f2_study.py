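"""Simulate a study-scale B73xA188 F2 callus-type experiment.

Builds the default ten-chromosome genome with the five-QTL architecture,
simulates 2194 embryos, selects 100 extreme Type I and 100 extreme Type II
calli, and degrades the selected genotypes to GBS-like observations.
"""

import numpy as np

from callusmap import simdata

cfg = simdata.default_config(seed=1)
truth = simdata.simulate_f2(cfg)

print(f"embryos simulated:        {cfg.n_embryos}")
print(f"Type II fraction:         {truth.phenotype.mean():.3f}")
print(f"selected extremes:        {len(truth.selected_type1)} XT-I + "
      f"{len(truth.selected_type2)} XT-II")

selected = truth.selected_type1 + truth.selected_type2
gbs = simdata.degrade_to_gbs(truth, individuals=selected)
missing = (gbs.calls == -1).mean()
print(f"SNPs per individual:      {gbs.n_sites}")
print(f"missing call fraction:    {missing:.3f}  (target ~0.20)")

# the chromosome-6 QTL carries the A188-favorable allele: its A188 dosage
# should be enriched among the Type II extremes
qi = [q.chrom for q in cfg.qtls].index("chr6")
i1 = [truth.individuals.index(i) for i in truth.selected_type1]
i2 = [truth.individuals.index(i) for i in truth.selected_type2]
print(f"chr6 A188 dosage, XT-I:   {truth.qtl_dosage[qi, i1].mean():.2f}")
print(f"chr6 A188 dosage, XT-II:  {truth.qtl_dosage[qi, i2].mean():.2f}")
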