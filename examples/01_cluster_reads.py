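"""Cluster a small synthetic read set and inspect the cluster cores.

Generates two 3 kb genomes with distinct composition, samples 2x-coverage
reads, groups them by shared 30-mers, merges groups by tetranucleotide
k-means (k detected automatically), and extracts each cluster's core — the
pairwise non-overlapping reads that would be submitted to similarity search.
"""

from corebin import pipeline, synthetic
from corebin.pipeline import PipelineConfig
from corebin.synthetic import SimConfig

cfg = SimConfig(n_genomes=2, genome_length=3000, coverage=2.0, seed=42)
genomes, tree = synthetic.simulate_genomes(cfg)
reads = synthetic.simulate_reads(genomes, cfg)

result = pipeline.run_cluster(reads, PipelineConfig(seed=42))

print(f"reads:            {len(reads)}")
print(f"overlap groups:   {len(result.groups)}")
print(f"clusters (auto k): {len(result.clusters)} (k-means k = {result.chosen_k})")
core = result.core_read_ids
print(f"core reads:       {len(core)} ({len(core) / len(reads):.0%} of all reads)")
print()
print("Only the core reads go to the aligner; the rest of each cluster")
print("inherits the label computed from its core's hits.")
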