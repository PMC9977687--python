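# devcomp

Comparative developmental transcriptomics toolkit: soft clustering of
stage-series expression profiles, cross-species orthogroup-overlap
heterochrony detection, Jensen–Shannon divergence (JSD) stage matching
with bootstrap, TF-class/phylostratum enrichment, and a synthetic-data
generator with planted ground truth so the whole pipeline is testable
offline.

## What it does

- **expression** — TSV expression table IO; replicate averaging;
  median-of-ratios size-factor normalization; the strict TPM > 2
  expressed-gene rule; per-column quantile transform to uniform [0, 1];
  classic across-sample quantile normalization.
- **clustering** — fuzzy c-means on z-scored profiles with an
  empirically estimated fuzzifier, minimum-centroid-distance scan and an
  explicit elbow rule (max forward second difference) for choosing k.
- **overlap** — OrthoFinder-style orthogroup parsing; upper-tail
  hypergeometric tests for every cluster pair; BH/Bonferroni adjustment;
  quadrant relative-similarity (RS) statistic; extraction of
  heterochronically shifted one-to-one orthologue sets; averaged
  (optionally LOWESS-smoothed) set dynamics.
- **jsd** — stage-pair JSD grids in bits over one-to-one orthologues;
  bootstrap mean/SD (resampling orthologue pairs); adjusted
  (per-orthologue), globally normalized and per-comparison relative
  variants; gene-wise JSD decomposition and similarity-driver extraction
  at 25% of the gwJSD density mode.
- **enrichment** — TF-class assignment from identifier catalogues;
  two-tailed Fisher representation tests per cluster; 75th-percentile
  phylostratum expression summaries; strictly tissue-restricted
  anterior/posterior gene sets; per-stage Student's t contrasts with
  Bonferroni correction.
- **simulate** — multi-species count/TPM matrices from Gaussian-bump
  expression archetypes with negative-binomial noise, shared single-copy
  orthologue cores, planted heterochronic shifts and planted label
  enrichments, all returned with a truth bundle.

## CLI

```sh
devcomp simulate --out data/ --seed 7          # synthetic bundle + truth
devcomp cluster  --matrix norm.tsv --k-range 2:9 --seed 7 --out clust/
devcomp overlap  --assignments-a a.tsv --assignments-b b.tsv \
                 --species-a A --species-b B --orthogroups orthogroups.tsv \
                 --quadrants quadrants.yaml --out overlap/
devcomp jsd      --species-a a.tpm.tsv --species-b b.tpm.tsv \
                 --orthologues pairs.tsv --bootstrap 250 --seed 7 \
                 --drivers S04:S04 --out jsd/
devcomp enrich   --assignments clust/assignments.tsv \
                 --annotation annotation.tsv --label-kind tf --out enrich/
devcomp run      --out run/ --seed 7           # full pipeline, one manifest
```

`devcomp run` executes simulate → normalize → cluster → overlap → jsd →
enrich with per-stage seeds split from one root seed; reruns with the
same seed are byte-identical. Every output table is TSV with a
provenance header comment and 6-significant-digit formatting.

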