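"""Estimate genome size from reads by k-mer frequency analysis.

Error-free 150 bp reads at 30x coverage are drawn from a 100 kb genome;
canonical 17-mers are counted and the genome size is estimated as the
number of k-mer occurrences above the error cutoff divided by the
(parabola-refined) coverage-peak depth.
"""

from paleodup import simcore, survey

genome = simcore.random_genome(100_000, seed=4)
reads = simcore.simulate_reads(genome, coverage=30, read_length=150, seed=5)
hist = survey.count_kmers(reads, k=17)
result = survey.estimate_genome_size(hist)

true_size = sum(len(s) for s in genome.values())
print(f"reads:            {len(reads)} x 150 bp")
print(f"k-mer occurrences: {hist.total_kmers}")
print(f"peak depth:       {result.peak_depth} (refined {result.refined_peak_depth:.2f})")
print(f"estimated size:   {result.genome_size_bp:,.0f} bp")
print(f"true size:        {true_size:,} bp "
      f"({100 * (result.genome_size_bp / true_size - 1):+.1f}% error)")
# The peak depth tracks coverage * (L - k + 1) / L; dividing the counted
# occurrences by it recovers the genome length.
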