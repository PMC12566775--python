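# Desk-scale demo of the full pipeline: a four-chromosome genome with two
# QTLs of opposite parental origin, 50+50 selected extremes, and reduced
# permutation count.  Run with:
#   callusmap run --config examples/demo_config.yaml --out demo_run
seed: 2024
sim:
  chromosome_lengths_cm: [120.0, 110.0, 100.0, 90.0]
  n_embryos: 500
  n_select_per_class: 50
  snp_density: 3.0
  bulk_size: 25
  n_genes: 1200
  qtls:
    - {chrom: chr1, pos_cm: 60.0, beta: -1.1}
    - {chrom: chr3, pos_cm: 40.0, beta: 1.0}
scan:
  n_perm: 100
  step_cm: 2.0
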