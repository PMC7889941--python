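# xtalk

Directional cell-to-cell communication scoring from bulk and single-cell
transcriptomes, built around a curated multi-subunit ligand–receptor
database.

A "central" cell population is connected to one or more "partner"
populations: expression is restricted to database genes, max-scaled per
gene onto [0, 10] (the per-gene maximum is the mean of the top 5% of
values; outliers cap at 10), and each interaction is scored as the product
of the ligand-side and receptor-side values, where multimeric sides combine
their subunits with a geometric mean (so a missing chain zeroes the
interaction). Per-interaction scores sum into a global directional score,
which can be normalized to a reference condition and linearly rescaled onto
[1, 10] for network display. Replicate-wise score distributions are
compared with two-sided Wilcoxon rank-sum tests and Benjamini–Hochberg
adjustment; single-cell cluster scores can be stress-tested by seeded
subsampling.

## Layout

- `xtalk.lr_database` — load/filter/validate the interaction database; a
  curated database of 380 interactions (194 cytokine interactions in 7
  named subfamilies) ships with the package (`xtalk/data/lr_pairs.tsv`).
- `xtalk.expression` — dense tables, MTX sparse triplets, annotations,
  cluster averaging, restriction to database genes.
- `xtalk.scaling` — per-gene top-fraction max-scaling to [0, 10].
- `xtalk.scoring` — per-interaction and global scores, family
  contributions, normalization, [1, 10] rescaling.
- `xtalk.stats` — partner/condition score distributions, Wilcoxon + BH,
  subsampling robustness.
- `xtalk.viz` — network map, stacked family barplot, balloon plot, p-value
  heatmap; every figure has an exact companion TSV.
- `xtalk.synthetic` — seeded toy databases and datasets with closed-form
  expected scores, used as test oracles.
- `xtalk.cli` — `xtalk` command-line entry point.

## CLI

All commands read a YAML config (unknown keys are rejected; flags override
config values) and write a `manifest.json` with input hashes, parameters
and seed into the output directory.

```sh
xtalk validate-db -c config.yaml          # database validation report
xtalk score       -c config.yaml          # score tables + all four figures
xtalk compare     -c config.yaml          # Wilcoxon/BH p-value tables + heatmap
xtalk subsample   -c config.yaml          # subsampling robustness report
```

Minimal scoring config:

```yaml
central: central.tsv                # genes x samples, first column = gene
partners: partners.tsv
central_annotation: central_annotation.tsv   # sample_id <TAB> condition
partner_annotation: partner_annotation.tsv   # sample_id <TAB> cell type
direction: out                      # ligands from central, receptors from partners
outdir: out
# database: my_pairs.tsv            # defaults to the shipped database
# families: [Cytokine]              # optional database filters
# reference_condition: cond0        # normalize scores to this condition
```

Defaults follow the published parameterization: scaling top fraction 0.05,
balloon-plot contribution cutoff 10, significance display threshold 0.1.

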