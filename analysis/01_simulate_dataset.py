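#!/usr/bin/env python
"""Generate the synthetic yolk-sac SAGE-Seq study used by all later steps.

Five embryonic days (E13-E21), three libraries each, a 300-gene
transcriptome with planted anchor defects, a declining erythropoietic
compartment (library share 0.5 -> 0.05), and reads with 0.5% substitution
errors.  Writes FASTA/FASTQ/metadata/truth under results/data/.
"""

import pathlib

from sagesac.synthetic_data import SimulationConfig, simulate_dataset, write_dataset

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "data"

config = SimulationConfig(
    n_genes=300,
    depth=20_000,
    epsilon=0.005,
    effect_size_ln=0.5,
    erythroid_gene_fraction=0.3,
    seed=11,
)

ds = simulate_dataset(config)
paths = write_dataset(ds, OUT)
ds.expected_statuses.to_csv(OUT / "expected_statuses.tsv", sep="\t")

n_reads = sum(len(r) for r in ds.reads.values())
print(f"wrote {len(paths)} files under {OUT}")
print(f"transcripts: {config.n_genes}, retained tags: "
      f"{len(ds.reference.retained_genes)}")
print(f"libraries: {len(ds.reads)}, total reads: {n_reads}")
print("class counts:", ds.truth.gene_table["class"].value_counts().to_dict())
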