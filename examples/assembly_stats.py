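"""Assembly summary statistics (lengths, scaffold/contig counts, N50).

Builds a small fragmented assembly with N-gapped scaffolds and prints the
six standard summary statistics.  On a real assembly, replace the simulated
object with `read_fasta("assembly.fasta")`; a strict minimum scaffold
length (e.g. > 1,000 bp) is applied before anything is computed, the
convention used when short scaffolds would otherwise dominate the counts.
"""

from microsynt import summarize_assembly
from microsynt import synthetic_data as sd

params = sd.SimParams(
    genome_size=2_000_000, n_chromosomes=2, n_inversions=0, n_translocations=0,
    mean_scaffold_len=150_000, gaps_per_mb=20.0,
)
genome, _, _, _ = sd.simulate_genome_pair(params, seed=3)

stats = summarize_assembly(genome.assembly, min_scaffold_len=0, min_gap=10)
for key, value in stats.as_dict().items():
    print(f"{key}\t{value}")
# total_sequence_length counts real bases only; total_assembly_length spans
# the estimated gaps (N runs) as well.  Scaffold N50 is computed on gapped
# spans, contig N50 on the gap-free segments obtained by cutting at every
# run of >= 10 N.
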