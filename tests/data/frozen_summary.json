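{
  "config_sha256": "ed73c4892bc9",
  "n_cytoplasmic": 12,
  "n_filtered": 59,
  "n_nuclear": 26,
  "n_tested": 341,
  "seed": 7,
  "tool_version": "0.1.0",
  "top_enrichment_term": "membrane_trafficking"
}
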