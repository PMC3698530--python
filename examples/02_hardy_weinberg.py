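"""Exact test of Hardy-Weinberg proportions.

The test conditions on the observed allele counts (Levene's
distribution) and sums the probability of all genotype tables no more
probable than the observed one — by complete enumeration when feasible,
by Monte-Carlo pairing of the allele-copy multiset otherwise. A cohort
simulated under random mating should not reject; one simulated with
inbreeding should.
"""

from hlapop import (
    GenotypeCountTable,
    SimulationConfig,
    exact_hwe_test,
    make_haplotype_spectrum,
    simulate_cohort,
)

spectrum = make_haplotype_spectrum(
    SimulationConfig(loci=("B",), alleles_per_locus=(4,))
)

for f, label in [(0.0, "random mating"), (0.5, "inbreeding f=0.5")]:
    cohort = simulate_cohort(spectrum, n=300, f=f, seed=11)
    table = GenotypeCountTable.from_cohort(cohort, "B")
    result = exact_hwe_test(table, method="monte_carlo",
                            mc_samples=20_000, seed=11)
    print(f"{label:20s} p = {result.p_value:.4f}  ({result.method}, "
          f"{result.mc_samples} samples)")

# a table small enough to enumerate completely
tiny = GenotypeCountTable("A", {("a", "a"): 1, ("b", "b"): 1})
r = exact_hwe_test(tiny)
print(f"two-homozygote toy   p = {r.p_value:.4f}  "
      f"({r.method}, {r.tables_enumerated} tables)")
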