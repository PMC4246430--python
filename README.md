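# sagesac

Tag-based quantification and time-course analysis of SAGE-Seq
experiments, built around the embryonic chicken yolk sac: a tissue whose
libraries mix endodermal epithelial cells with an erythropoietic
compartment that shrinks from roughly half of the transcriptional output
near E13 to a few percent by hatch.  The package takes a transcriptome
FASTA and per-library FASTQ reads and produces gene counts, normalized
expression, per-gene differential-expression calls across embryonic
days, temporal-pattern clusters, and an epithelial/erythroid gene
partition with a renormalized epithelial re-analysis.  A truth-known
synthetic-data generator makes the whole pipeline testable end-to-end
with no downloads.

## The method in brief

- **Tag reference.** Each mRNA contributes at most one 23-bp tag starting
  at the 3'-most NlaIII site (CATG); transcripts without an anchor, with
  fewer than 23 bases from the anchor to the 3' end, with ambiguous
  bases in the tag, or sharing a tag with another transcript are
  excluded.
- **Read processing & matching.** Reads are trimmed to 23 bp and kept at
  mean phred >= 20, then matched bowtie-style: Hamming distance <= 2,
  mismatch phred sum <= 70, at most 10 candidate hits, best stratum by
  (mismatches, quality sum); only uniquely assigned reads are counted.
- **Normalization.** Upper-quartile scaling per library (75th percentile
  over genes with nonzero total), ln(x+1) transform, and exclusion of
  genes with mean normalized count < 8.
- **Differential expression.** Per gene, y ~ NB(mu, phi) with
  Var = mu + phi mu^2, log link, day as a categorical factor and library
  offsets; dispersion by Cox–Reid adjusted profile likelihood; the
  overall day effect tested by a fixed-dispersion LRT referred to
  F(df, residual df), BH-adjusted at 5% FDR; Wald t contrasts for
  (E13,E17), (E17,E21), (E15,E19), (E19,E21), BH at 10% per contrast;
  fold changes on the normalized count scale.
- **Clustering.** Per-day mean profiles of significant genes,
  standardized per gene, Ward/Euclidean hierarchical clustering, one
  dendrogram cut at nested levels (3/8/21 by default).
- **Separation.** Clusters enriched for erythroid markers (odds ratio
  >= 2, hypergeometric p < 0.01) are labeled erythropoietic; the
  epithelial remainder is upper-quartile renormalized on its own and the
  four contrasts re-run, removing the compositional bias that makes
  stable epithelial genes look up-regulated as the erythroid compartment
  recedes.

Details, defaults and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about two minutes total) and write their tables under `results/`:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_build_reference.py
...
python analysis/08_evaluate_against_truth.py
```

Step 01 plants a 300-gene transcriptome (10% each of no-anchor,
too-short and duplicated-tag transcripts) and 15 libraries of 20,000
reads.  Step 02 prints the reference filtering:

```
tag-reference status counts:
  retained        210
  no_anchor       30
  too_short       30
  ambiguous_base  0
  redundant       30
unique mappable tags: 210
```

Steps 03–05 count tags and fit the NB GLMs:

```
count matrix: 210 genes x 15 samples, total counts 212253
genes passing the mean>=8 filter: 189/210
genes tested: 189; significant at 5% FDR: 108
  contrast E13 vs E17: 109 significant at 10% FDR
  contrast E17 vs E21: 68 significant at 10% FDR
```

The 108 significant genes are the genes whose expected expression truly
changes across days (planted templates plus the declining erythroid
mixture); the contrasts localize the changes in time.  Step 07 labels 62
genes erythropoietic from 29 supplied markers and re-runs the contrasts
on the renormalized epithelial subset, and step 08 scores everything
against the planted truth:

```
cluster_ari: 0.7026
count_exact_fraction: 0.9816
count_pearson_r: 1.0000
de_empirical_fdr: 0.0000
erythroid_recall: 1.0000
partition_accuracy: 0.8426
```

Count recovery is near-exact (the 1.8% of differing cells are reads lost
to the planted 0.5% substitution errors), no false DE calls are made,
and every erythroid gene is recovered by the marker-enrichment labeling.

The same pipeline is scriptable from a config file:

```sh
sagesac run --config run.yaml --out outdir/
```

with per-stage caching, checksummed manifests, and subcommands
(`build-ref`, `preprocess`, `count`, `qc`, `normalize`, `de`, `cluster`,
`separate`, `simulate`) for individual stages.

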