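# End-to-end fixture: synthetic dataset -> localization -> enrichment -> qPCR.
seed: 7
simulate:
  n_genes: 400
  replicates: 3
  frac_nuclear_shifted: 0.05
  frac_cytoplasmic_shifted: 0.005
  shift_log2: -1.5
  noise_log2_sd: 0.2
  frac_multilocus: 0.05
  frac_subthreshold: 0.1
localization:
  threshold: -1.0
  alpha: 0.05
  scale: log2
enrichment:
  n_sets: 15
  enriched_set_fraction: 0.6
  set_size: 30
  top: 10
qpcr:
  n_targets: 3
  noise_log2_sd: 0.1
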