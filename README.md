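# dgescreen

Combinatorial differential-gene-expression screening of druggable target
genes across cell types and brain regions.

Given a cells × genes expression matrix of depth-normalised counts (CPM),
a per-cell annotation table (`region_label`, `subclass_label`,
`class_label`), and a druggable-target catalogue partitioned into nine
target classes, the pipeline identifies *differentially higher expressed
target genes* (DHETGs) for a target cell type: genes that are
significantly (Wilcoxon rank-sum, Bonferroni or Benjamini–Hochberg
corrected) and substantially (default: more than three-fold, i.e.
log2 difference > 1.585) higher expressed in the target set than in a
contrast set, optionally constrained by the spread in expressing-cell
fractions (beta) and by near-absence of expression in the contrast set.

Contrast strategies:

- **intra-regional, conservative (one-vs-one)** — the target type against
  every other cell type of the region; DHETGs are the intersection across
  all pairwise comparisons (majority-rule combination is also available);
- **intra-regional, non-conservative (one-vs-all)** — the target against
  the pooled GABAergic and pooled glutamatergic cells (target removed from
  its own pool), intersected;
- **inter-regional** — the same cell type at home vs its counterpart in
  pooled region groups (e.g. combined motor or sensory areas).

A synthetic-data generator (zero-inflated log-normal CPM with planted
selective, graded-"ladder", and beta-only genes plus a ground-truth answer
key) stands in for the large public atlases, so everything here runs
offline at desk scale.

## Layout

| module | contents |
| --- | --- |
| `dgescreen.core` | `ExpressionDataset`, selectors, loaders (dense CSV/TSV, Matrix Market) |
| `dgescreen.catalog` | target-catalogue build: orthologue mapping, dedup, alias alignment |
| `dgescreen.stats` | log2(1+CPM), rank-sum p (exact/asymptotic), Bonferroni/BH, per-contrast stats |
| `dgescreen.criteria` | DHETG criteria regimes and fold-sensitivity analysis |
| `dgescreen.contrasts` | contrast plans, intersection / Venn / majority-rule combination |
| `dgescreen.reporting` | per-class hit shares, cross-cell-type multiplicity report |
| `dgescreen.simulate` | synthetic datasets, planted effects, population-level answer key |
| `dgescreen.pipeline` / `dgescreen.cli` | config-driven runs, `dgescreen` command |

## CLI

```sh
dgescreen simulate --config sim.json --out-dir data/        # synthetic data
dgescreen catalog  --targets targets.tsv --orthology orth.tsv \
                   --aliases alias.tsv --dataset-genes genes.txt \
                   --out catalog.tsv --report-out report.json
dgescreen screen   --config run.yaml                        # full screen
dgescreen report   --hits hits.json --catalog catalog.tsv --out-dir rep/
```

`screen` consumes a JSON/YAML run config (dataset paths, plans, one or
more named criteria regimes, output directory — see the
`dgescreen.pipeline` docstring for the schema) and writes per-contrast
statistics CSVs, selection JSONs (per-contrast sets, full intersection,
exclusive and cumulative Venn cells, majority-rule sets), and a manifest.
Exit codes: 0 success, 2 config/schema error, 3 data integrity error,
4 other failures.

A note on `diff_mean`: it is the difference of set means of log2(1+CPM),
so the linear fold threshold f translates to a cutoff of log2(f); all
criteria comparisons are strict inequalities.

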