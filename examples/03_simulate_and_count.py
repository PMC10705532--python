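"""Simulate reads from a heterozygous genome and extract k-mer features.

Normalized counts are in per-haploid-copy units: a k-mer present once per
haplotype sits near 2.0 in a wild-type diploid, near 1.0 when one haplotype
has lost it, and near 0.0 when both have.
"""

import numpy as np

from svkg import (
    ALL_GENOTYPES, ReadSimParams, build_kmer_index, count_kmers,
    default_blueprint, generate_haplotype_panel, normalize, simulate_reads,
)
from svkg.dataset import simulate_sample_genome

panel = generate_haplotype_panel(default_blueprint())
index = build_kmer_index(panel)  # k=21, every 30th k-mer kept
print(f"feature index: {index.n_features} keys subsampled from "
      f"{index.n_full} k-mers, {index.control_keys.size} control k-mers")

het37 = ALL_GENOTYPES[1]  # WT/DEL37
genome = simulate_sample_genome(panel, het37, 0, 1)
reads = simulate_reads(genome, ReadSimParams(coverage=30, seed=7))
print(f"simulated {reads.n_pairs} read pairs at 30x from a {het37} genome")

vector = normalize(count_kmers(reads, index, sample_id="demo"), "per-haploid-copy")
print(f"estimated per-haploid-copy depth (normalizer): {vector.normalizer:.1f}")

control_mean = float(np.mean(vector.control_counts / vector.normalizer))
print(f"mean normalized control-key count: {control_mean:.2f} (expect ~2.0)")

# keys inside the del3.7-deleted span that occur exactly once in a wild-type
# haplotype: absent from the deleted haplotype, so a heterozygote sits ~1.0
from svkg import DEFAULT_SVS
cut = DEFAULT_SVS["del3.7"].deleted_interval(panel[0])
span_counts = count_kmers([panel[0].sequence[cut[0] : cut[1]]], index).counts
hap_counts = count_kmers([panel[0].sequence], index).counts
single_copy = (span_counts == 1) & (hap_counts == 1)
mean_span = float(np.mean(vector.counts[single_copy]))  # already normalized
print(f"mean normalized count over {int(single_copy.sum())} single-copy k-mers "
      f"in the deleted span: {mean_span:.2f} (expect ~1.0 in a heterozygote)")
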