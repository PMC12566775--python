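"""From noisy SNP calls to GBS segment (bin) markers.

Segments each selected individual's calls, flags individuals whose
discernible recombination count exceeds twice the 2L-Morgan expectation,
and harmonizes the retained individuals' segments into population bin
markers.
"""

from callusmap import binmarkers, simdata

cfg = simdata.default_config(seed=1, n_embryos=800, n_select_per_class=60)
truth = simdata.simulate_f2(cfg)
selected = truth.selected_type1 + truth.selected_type2
gbs = simdata.degrade_to_gbs(truth, individuals=selected)

# QC pass: light smoothing so error-driven breakpoints stay visible
qc_segs = binmarkers.call_segments_all(gbs, binmarkers.QC_SEGMENT_PARAMS)
expected = binmarkers.expected_recombination_count(cfg.genetic_map)
retained, report = binmarkers.filter_individuals(qc_segs, expected, 2.0)
print(f"expected recombination events per F2: {expected:.1f}")
print(f"mean observed (QC segmentation):      "
      f"{report['recombination_events'].mean():.1f}")
print(f"individuals retained:                 {len(retained)}/{len(selected)}")

# mapping pass: default smoothing (window 5, min 3 SNPs per segment)
segsets = binmarkers.call_segments_all(gbs.subset_individuals(retained))
bins = binmarkers.harmonize_bins(segsets, cfg.genetic_map)
print(f"bin markers after harmonization:      {bins.n_bins}")
print(f"mean segments per individual:         "
      f"{sum(len(s.segments) for s in segsets) / len(segsets):.1f}")
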