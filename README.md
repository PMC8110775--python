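# idhres

Reusable analysis pipeline for longitudinal multi-omics studies of
IDH-inhibitor resistance in AML, exercised end-to-end on seeded synthetic
cohorts. The package implements:

- **`idhres.simulate`** — a synthetic multi-omics cohort generator
  (~60 patients by default) with planted structure: responder/nonresponder
  split, two latent methylation clusters (cluster 1 hypomethylated and
  DNMT3A-enriched, cluster 2 hypermethylated with elevated stemness
  expression and a nonresponse bias), co-occurring driver mutations with
  clonal/subclonal cancer-cell fractions, longitudinal VAF trajectories with
  relapse acquisitions, post-treatment demethylation, and plasma 2HG
  dynamics. Every planted fact is recorded in a truth JSON sidecar.
- **`idhres.variants`** — somatic variant filter cascade (coverage ≥ 15×,
  tumor VAF ≥ 5%, normal-allele limits, protein-altering consequences,
  population frequency < 0.14%) and a 4-tier hierarchical confidence
  classifier (exact catalog match → LoF-in-TSG → same position →
  within-3-residues + damaging).
- **`idhres.clonal`** — CCF estimation (diploid copy-neutral heterozygous:
  CCF = min(1, 2·VAF)), relative mutation timing, IDH-clearance calling
  (≥ 75% VAF decrease, boundary inclusive), relapse emergence/selection
  detection with pathway grouping, and single-cell clone-independence
  testing (Fisher exact).
- **`idhres.methylation`** — probe filtering (SNP/chrX/chrY), top-variance
  promoter CpG selection, consensus k-means clustering (cluster 2 is always
  the hypermethylated group), Welch-t differential methylation with BH
  correction, and longitudinal delta-beta concordance.
- **`idhres.stemness`** — the published 17-gene stemness score (LSC17) as an
  exact linear combination, simplified differential expression, and a
  minimal preranked running-sum enrichment statistic with permutation p.
- **`idhres.stats`** — Fisher exact enrichment with odds ratios and Woolf
  CIs, response rates, ROC/AUROC (Mann–Whitney with tie correction),
  IRLS logistic regression with separation detection, starburst
  methylation×expression integration, and two-group log-rank comparison.
- **`idhres.patterns`** — rule-based classification of relapse biology into
  three evolution patterns from joint 2HG/methylation dynamics and
  homolog-switch evidence.

## CLI

```bash
idhres simulate --seed 1 --out cohort/                 # synthetic cohort bundle
idhres variants classify --calls cohort/variants.tsv \
    --resources cohort/resources --out drivers.tsv     # filter + tier
idhres clonal clearance --calls cohort/variants.tsv --out clearance.tsv
idhres clonal events --baseline base.tsv --relapse rel.tsv --out events.tsv
idhres methyl cluster --beta cohort/beta_baseline.tsv \
    --meta cohort/probe_meta.tsv --out clusters.tsv
idhres stemness score --expression cohort/expression_baseline.tsv --out scores.tsv
idhres patterns classify --cohort-dir cohort/ --out patterns.tsv
idhres run-all --seed 1 --out report/                  # full end-to-end analysis
```

All file formats are plain UTF-8 TSV (MAF-like variant tables, probes × samples
beta matrices, genes × samples expression matrices) plus a truth JSON sidecar.

## Modeling notes

- The CCF model is an explicit assumption (diploid, copy-neutral,
  heterozygous), matching the generator's ground truth; no copy-number
  inference is performed.
- Differential methylation/expression use Welch t-tests on beta / log2
  values rather than moderated or count-based models; the analysis target
  (BH-FDR significance sets and effect directions) is preserved.
- Absolute LSC17 score scale depends on upstream expression normalization;
  only within-matrix comparisons are meaningful.
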