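# hlapop

Desk-scale HLA population genetics and peptide-binding profile analysis.

HLA loci (HLA-A, -B, -C, -DRB1, -DQB1, -DQA1) are the most polymorphic
genes in the human genome and sit in a region of strong linkage
disequilibrium, which makes it hard to tell *which* allele on an
associated haplotype is causal — for example for the HLA-linked forms of
drug-induced liver injury (DILI). `hlapop` implements the standard
in-silico toolkit a typed cohort is run through:

* **Allele / carrier frequencies** by direct counting: AF_a =
  copies(a) / 2n, GF_a = carriers(a) / n, on the individuals typed at
  each locus.
* **Exact Hardy-Weinberg test** at multiallelic loci. Conditional on the
  allele copy counts n_a, a genotype table *t* with heterozygote count H
  has Levene probability
  P(t) = n!·Πₐn_a!·2^H / [(2n)!·Π c_ij!], and the p-value is
  Σ P(t′) over tables with P(t′) ≤ P(t) — by complete enumeration or
  Monte-Carlo pairing of the allele-copy multiset.
* **EM haplotype frequencies** from unphased multilocus genotypes:
  E-step weights each phase-consistent haplotype pair (h_i, h_j) by
  (2−δ_ij)h_i h_j normalised per individual; M-step sets h to expected
  copy counts / 2N.
* **Multiallelic LD**: Lewontin D′_ij per allele pair and Hedrick's
  frequency-weighted summary D′ = Σ_ij p_i q_j |D′_ij| (plus the
  Cramér's-V analogue W_n).
* **Haplotype networks** in GraphViz DOT, with edges drawn only above a
  display threshold (e.g. >5%) or styled bold/dotted around a bold
  threshold (e.g. >1%), and alleles of interest highlighted.
* **Binding-profile distance trees**: random k-mer peptides from a
  proteome, per-allele affinity-score profiles in [0, 1] (≈0.4 weak
  binder, ≈0.6 strong binder), pairwise distance 1 − Pearson r, and a
  deterministic neighbor-joining tree (exact on additive matrices).
* **Synthetic data**: haplotype spectra with a tunable LD weight
  λ (product spectrum → bijective pairing), diploid cohorts by random
  union of haplotypes with optional inbreeding f, and a motif-based
  surrogate binding scorer with shared-motif groups — so every stage
  runs and can be validated without external data or trained predictors.

## Worked example

`examples/03_haplotypes_and_ld.py` simulates 500 individuals from a
known two-locus spectrum with LD weight 0.7 and re-estimates it by EM:

```
EM: 10 iterations, converged=True, logL=-1420.13
haplotype                      true     EM
DRB1*01:01~DQB1*01:01         0.267  0.274
DRB1*02:01~DQB1*02:01         0.267  0.271
DRB1*03:01~DQB1*03:01         0.267  0.264
...
overall D': true 0.700, estimated 0.723 (Wn 0.715)
```

The three "diagonal" haplotypes carry the bijective LD mass, EM recovers
every frequency to well under 0.03, and the frequency-weighted D′
estimated from unphased data lands within 0.03 of the generating
spectrum's value. The other examples cover frequency tables and
planning arithmetic (`01`), the exact HWE test accepting a random-mating
cohort and rejecting an inbred one (`02`), DOT haplotype networks
(`04`), and NJ trees that cluster shared-motif alleles (`05`).

A thin CLI wraps the same stages
(`hlapop simulate | freq | hwe | haplo | ld | graph | peptides |
bindtree | pipeline`); every stochastic command requires `--seed` and
writes a JSON run manifest alongside its output.

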