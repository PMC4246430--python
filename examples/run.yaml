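# Full-pipeline run on a synthetic dataset.  Replace the `simulate`
# block with an `inputs` block (fasta / metadata / fastq_dir) to analyze
# real libraries.
seed: 11
simulate:
  n_genes: 150
  depth: 10000
  epsilon: 0.005
  effect_size_ln: 0.6
params:
  cuts: [3, 6, 12]
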