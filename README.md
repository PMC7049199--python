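# exohub

Rare-variant case-case exome analysis: separate two diagnostic cohorts (ASD
vs. SCZ) from annotated rare coding variants, then identify per-disease
co-mutation "hub" genes.

The pipeline has six stages:

1. **simulate** — synthetic two-cohort variant-call generator with planted
   ancestry structure, class-discriminative genes, co-mutation hub modules,
   and deliberate filter failures, plus a machine-readable truth record
   (real cohorts of this kind are controlled-access, so everything downstream
   is exercised on synthetic data).
2. **filter** — variant selection: coding consequence in
   {frameshift_deletion, frameshift_insertion, frameshift_substitution,
   nonsynonymous_SNV, stopgain, stoploss}, functional type in
   {exonic, exonic_splicing, intronic_splicing}, MAF ≤ 0.01, and per-call
   evidence alt_reads ≥ 4, depth ≥ 10, GQ ≥ 90 (all inclusive); assembles the
   samples × variants 0/1/2 genotype matrix.
3. **adjust** — population-structure correction: top principal axes of
   variation of the (allele-frequency-normalized) genotype matrix; every
   variant column and the ±1-coded phenotype are regressed on the axes by
   OLS, residuals rounded half-away-from-zero and capped to [−4, +4].
4. **features** — gene-level counts: per-sample signed sums of adjusted
   variant values per gene.
5. **train** — gradient-boosted regression trees (scikit-learn
   `GradientBoostingRegressor`) on the adjusted phenotype for both the
   SNV-based and gene-based representations; continuous predictions mapped to
   classes by sign; accuracy / precision / recall / NIR / exact binomial
   p-value / Clopper-Pearson CI on a balanced per-class 70:30 split plus
   stratified five-fold cross-validation; genes behind positive-importance
   features are extracted and the two gene lists intersected.
6. **hub** — within one class's cases, each overlapping gene is represented
   by its carrier set (gene count > 0); genes are clustered by Ward linkage
   on 1 − Jaccard distances between carrier sets; flat clusters are ranked by
   the cases-per-gene ratio b/a (b = unique carrier union, a = gene count)
   and the highest-ratio cluster is selected as the hub cluster.

## CLI

```sh
exohub run-all --seed 7 --out runs/demo          # full pipeline, default config
exohub run-all --config my.yaml --out runs/custom
exohub simulate --out runs/sim --seed 1 --vcf    # generator only (+ VCF export)
exohub filter --calls runs/sim/calls.tsv --out runs/sim/filtered.tsv
exohub adjust --calls runs/sim/filtered.tsv --truth runs/sim/truth.json --out runs/adj
exohub features --adjusted runs/adj/adjusted_matrix.tsv \
    --variant-map runs/adj/variant_gene_map.tsv --out runs/adj/gene_counts.tsv
exohub train --adjusted runs/adj/adjusted_matrix.tsv \
    --variant-map runs/adj/variant_gene_map.tsv --features gene --cv 5 --seed 1 --out runs/adj
exohub hub --gene-counts runs/adj/gene_counts.tsv \
    --genes runs/adj/important_genes_gene.tsv --class SCZ --out runs/adj
```

`run-all` writes every intermediate artifact (TSV/JSON/Newick, dendrogram
plots), a manifest with per-stage shapes and derived seeds, and a summary with
test/CV metrics, the overlapping-gene count, and per-class hub clusters
(a, b, ratio, coverage). Reruns with the same seed are byte-identical.

YAML config keys mirror `exohub.pipeline.RunConfig`; defaults reproduce the
reference settings (MAF 0.01, reads 4/10/90, 4 axes, 70:30 split, 5-fold CV,
±4 caps).

## Layout

```
src/exohub/
  simulate.py    synthetic cohort generator + truth record
  filtering.py   selection rules, genotype matrix
  stratify.py    axes of variation, residual adjustment, round & cap
  features.py    gene-level collapsing
  model.py       boosted trees, split/CV, metrics, gene extraction
  hubclust.py    carrier sets, Jaccard/Ward clustering, cluster ranking
  io.py          TSV + VCF 4.2 readers/writers
  pipeline.py    run-all orchestration, manifest
  cli.py         click CLI
```
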