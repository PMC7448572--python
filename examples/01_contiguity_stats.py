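"""Assembly contiguity statistics on a simulated three-chromosome genome.

Builds a small genome with spanned and unspanned gaps, then computes the
standard assembly-report statistics (N50/L50, gap counts, placed/unplaced
decomposition) from its AGP layout.
"""

from karyoscan import assembly_stats, stats_table
from karyoscan.simulate import SimConfig, simulate_genome

records, layout, truth = simulate_genome(SimConfig(seed=1))
stats = assembly_stats(layout, records)
print(stats_table({"simulated": stats}).to_string())
print()
print(
    f"Contig N50 {stats.contig_n50:,} bp means half of all assembled bases sit\n"
    f"in contigs at least that long; the {stats.n_spanned_gaps} spanned gaps\n"
    f"break scaffolds into contigs, and the {stats.n_unspanned_gaps} unspanned\n"
    f"gaps break chromosomes into scaffolds."
)
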