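"""Allele and carrier frequencies by direct counting.

Simulates a small HLA-typed cohort, counts allele copies and carriers at
one locus, and prints the frequency table. AF is the fraction of the
2n chromosomes carrying each allele; GF is the fraction of individuals
carrying at least one copy.
"""

from hlapop import (
    SimulationConfig,
    allele_frequencies,
    hwe_expected_counts,
    make_haplotype_spectrum,
    simulate_cohort,
)

cfg = SimulationConfig(loci=("DRB1",), alleles_per_locus=(5,), n=400, seed=42)
cohort = simulate_cohort(make_haplotype_spectrum(cfg), n=400, seed=42)

table = allele_frequencies(cohort, "DRB1")
print(f"locus DRB1, n_typed = {table.n_typed}")
print(table.table.round(3))

# Planning arithmetic: expected genotype counts under Hardy-Weinberg
# proportions for an allele at frequency 0.087 in 400 individuals.
e = hwe_expected_counts(p=0.087, n=400)
print(
    f"\nHWE expectation at p=0.087, n=400: "
    f"{e.expected_homozygotes:.2f} homozygotes (~{e.rounded_homozygotes}), "
    f"{e.expected_heterozygote_carriers:.2f} single-copy carriers"
)
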