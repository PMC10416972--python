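# nucyto

Nucleocytoplasmic mRNA distribution analysis for fractionated RNA-seq.

Starting from a gene-level FPKM matrix over a two-condition (control vs
repeat) x two-fraction (nuclear vs cytoplasmic) replicated design, `nucyto`:

- filters expressed genes (log2(FPKM) strictly above a threshold in every
  sample),
- computes per-replicate cytoplasmic/nuclear (C/N) ratios, per-condition
  means, the repeat-vs-control fold change, and a two-sided two-sample
  Student t-test per gene (log2 or linear ratio scale; Welch and
  Benjamini–Hochberg options),
- classifies genes as `nuclear_accumulated` (significant, fc < 1) or
  `cytoplasmic_accumulated` (significant, fc > 1) and exports volcano and
  row-z-score heatmap tables,
- runs exact hypergeometric over-representation analysis of a gene list
  against GMT gene sets with BH adjustment,
- computes qPCR C/N fold changes from Cq tables via 2^-dCt against
  fraction-specific housekeeping genes (nuclear: Malat1, cytoplasmic:
  GAPDH), normalized so the control ratio is 1,
- generates seeded synthetic datasets (expression matrix, sample sheet,
  locus map, gene sets, Cq tables) with known ground truth for end-to-end
  testing.

## CLI

```sh
# synthetic fixture with known truth
nucyto simulate --n-genes 1000 --seed 1 --outdir fixtures/

# localization statistics + volcano/heatmap exports
nucyto localize --matrix fixtures/matrix.tsv --samples fixtures/samples.tsv \
    --locus-map fixtures/locus_map.tsv --threshold -1.0 --alpha 0.05 \
    --scale log2 --out results.tsv --volcano volcano.tsv --heatmap heatmap.tsv

# over-representation analysis of a gene list against GMT sets
nucyto enrich --genes nuclear_genes.txt --gmt fixtures/sets.gmt --top 10 \
    --out enrich.tsv

# qPCR C/N fold change vs control
nucyto qpcr --cq fixtures/cq.tsv --out qpcr_fc.tsv

# full pipeline (simulate -> localize -> enrich -> qpcr), deterministic per
# (config, seed); writes results + summary.json into the run directory
nucyto run --config tests/data/run_fixture.yaml --outdir runs/demo
```

All inputs and outputs are plain TSV/GMT/YAML/JSON; result tables carry a
`# nucyto=<version> config=<hash>` provenance comment.

## Layout

- `src/nucyto/io_formats.py` — expression-matrix / sample-sheet / locus-map /
  GMT / result-table IO and gene-symbol aggregation
- `src/nucyto/localization.py` — filtering, C/N ratios, t-test,
  classification, volcano and heatmap exports
- `src/nucyto/enrichment.py` — hypergeometric ORA (log-space exact tail) and
  BH adjustment
- `src/nucyto/qpcr.py` — 2^-dCt relative expression and C/N fold change
- `src/nucyto/synthetic.py` — seeded generators with truth tables
- `src/nucyto/pipeline.py`, `src/nucyto/cli.py` — orchestration and the
  `nucyto` command
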