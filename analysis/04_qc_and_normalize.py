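#!/usr/bin/env python
"""PCA outlier screen, upper-quartile normalization, low-count filter.

Samples flagged by the within-day distance rule are dropped; the rest are
upper-quartile scaled, ln(x+1) transformed, and genes with mean
normalized count below 8 are excluded from model fitting.
"""

import pathlib

from sagesac.normalization import low_count_filter, normalize
from sagesac.qc_outliers import screen_outliers
from sagesac.tag_alignment import CountMatrix

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

cm = CountMatrix.from_tsv(ROOT / "counts.tsv", ROOT / "data" / "samples.tsv")
scores, flagged = screen_outliers(normalize(cm).values, cm.metadata)
scores.to_csv(ROOT / "qc_scores.tsv", sep="\t", index_label="sample_id")
print(f"flagged outlier samples: {flagged or 'none'}")

kept = cm.drop_samples(flagged)
kept.to_tsv(ROOT / "counts.qc.tsv")
kept.metadata.reset_index().to_csv(ROOT / "samples.qc.tsv", sep="\t", index=False)

norm = normalize(kept)
norm.values.to_csv(ROOT / "normalized.tsv", sep="\t", index_label="gene_id")
norm.norm_counts.to_csv(ROOT / "norm_counts.tsv", sep="\t", index_label="gene_id")
norm.scale_factors.to_frame().to_csv(
    ROOT / "scale_factors.tsv", sep="\t", index_label="sample_id"
)
retained = low_count_filter(norm.norm_counts)
(ROOT / "retained_genes.txt").write_text("".join(f"{g}\n" for g in retained))

print(f"scale factor range: {norm.scale_factors.min():.3f}-"
      f"{norm.scale_factors.max():.3f}")
print(f"genes passing the mean>=8 filter: {len(retained)}/{len(norm.genes)}")
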