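"""Partition a genome into forest/prairie domains from CpG-island positions.

Builds a synthetic CGI annotation, calls the gap-based partition, and
classifies 40-kb bins by CpG/SINE density medians.
"""

from fpseg import (
    SyntheticSpec,
    classify_bins_cpg_sine,
    generate_genome,
    partition_forest_prairie,
)

spec = SyntheticSpec(n_domains=12, domain_length_bins=(10, 20))
genome = generate_genome(spec, seed=7)

called = partition_forest_prairie(genome.cgi, genome.chrom_sizes,
                                  gap_threshold_bp=50_000, min_domain_bp=200_000)
print("planted domains:", len(genome.domains.df), "| called:", len(called.df))
print(called.df.head())
# Each row is one domain: forests (F) chain CGIs spaced < 50 kb apart,
# prairies (P) fill the CGI deserts between them.

cls = classify_bins_cpg_sine(genome.cpg_density, genome.sine_density)
for name in ("hChS", "hClS", "lChS", "lClS"):
    print(name, (cls.cls == name).sum(), "bins")
# hChS = above-median CpG AND SINE density; with correlated tracks most bins
# land in the two concordant classes (hChS forests, lClS prairies).
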