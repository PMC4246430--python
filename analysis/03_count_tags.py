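#!/usr/bin/env python
"""Trim and quality-filter reads, assign them to genes, build the count
matrix.

Reads are cut to 23 bp, screened at mean phred >= 20, then matched
against the tag reference under the bowtie-style contract (<=2
mismatches, mismatch-quality sum <= 70, <=10 hits, best stratum).  Only
uniquely assigned reads are counted.
"""

import json
import pathlib

from sagesac.read_processing import preprocess, read_fastq
from sagesac.tag_alignment import TagMatcher, count_assignments, read_sample_metadata
from sagesac.tag_reference import TagReference

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

ref = TagReference.from_tsv(ROOT / "ref.tags.tsv")
matcher = TagMatcher.from_reference(ref)
meta = read_sample_metadata(ROOT / "data" / "samples.tsv")

assignments, pre_stats = {}, {}
for sample in meta.index:
    reads = read_fastq(ROOT / "data" / f"{sample}.fq")
    kept, stats = preprocess(reads)
    pre_stats[sample] = stats
    assignments[sample] = matcher.match_all(kept)

cm, map_stats = count_assignments(assignments, meta, ref.retained_genes)
cm.to_tsv(ROOT / "counts.tsv")
with open(ROOT / "mapping_stats.json", "w") as fh:
    json.dump({"preprocess": pre_stats, "mapping": map_stats}, fh, indent=2)

pass_frac = sum(s["reads_kept"] for s in pre_stats.values()) / max(
    sum(s["reads_in"] for s in pre_stats.values()), 1
)
uniq = [s["unique_fraction"] for s in map_stats.values()]
print(f"quality-pass fraction: {pass_frac:.3f}")
print(f"unique fraction of mapped reads: "
      f"{min(uniq):.3f}-{max(uniq):.3f} across libraries")
print(f"count matrix: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} samples, "
      f"total counts {int(cm.counts.to_numpy().sum())}")
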