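"""Filter simulated read pairs for low-complexity and short-stretch artifacts.

Generates transcriptome-aligned read pairs with 10% homopolymer reads and
15% PCR duplicates, applies the k-mer complexity + CIGAR stretch filter,
then removes exact duplicates.
"""

from ntve.filtering import KmerFilterConfig, dedup_pairs, filter_pairs
from ntve.simulate import SimulationConfig, simulate_aligned_reads, simulate_transcriptome

config = SimulationConfig(n_genes=50, lowcomplexity_rate=0.10, duplicate_rate=0.15, seed=11)
sequences, annotations = simulate_transcriptome(config)
records = simulate_aligned_reads(config, annotations, "supernatant", sequences, n_pairs=2000)

kept, report = filter_pairs(records, KmerFilterConfig(k=21, min_unique_fraction=0.8, min_mapped_stretch=80))
deduped, n_duplicates = dedup_pairs(kept)

print("filter report:", report.as_dict())
print(f"duplicates removed after filtering: {n_duplicates}")
print(f"final pairs: {len(deduped) // 2}")
# The low-complexity drop count tracks the simulated homopolymer rate
# (~10% of 2000 pairs); duplicate pairs survive the complexity filter only
# if their source pair did, so the dedup count is a bit below 15%.
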