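# Methods

This note records the statistical models implemented in `hlapop`, the
defaults that matter, the numerical choices, and what the synthetic
generators do and do not emulate.

## Cohorts, nomenclature and counting

A cohort is a set of unrelated diploid individuals with unordered allele
pairs at up to six HLA loci (A, B, C, DRB1, DQB1, DQA1). Allele names
follow WHO nomenclature (`locus*ff:ff[:ff[:ff]]`, optional trailing `g`
for an ambiguity group that sequencing could not resolve). Genotype
pairs are normalised to lexicographic order, so pair order in input
files is not significant. Missingness is tracked per locus: an
individual untyped at DQB1 still contributes to HLA-A counts, and all
frequencies are computed on `n_typed` at the locus in question.

`g`-suffixed names are analysed as distinct allele labels by default;
a user-supplied two-column mapping can reallocate them to plain names
(`Cohort.map_alleles`). Truncating an allele at or below a g-group's
field resolution drops the suffix, because the group is only defined at
its full resolution; the truncated name is then valid plain
nomenclature. Display rounding (AF to 3 decimals, carrier percentage to
1 decimal) is purely a serialisation convention; in-memory values are
full precision, and the TSV writer emits exact integer counts so tables
round-trip.

## Exact Hardy-Weinberg test

Conditional on observed allele copy counts `n_a`, Levene's distribution
gives the null probability of genotype table `t` with counts `c_ij` and
heterozygote count `H`:

    P(t | n) = n! Π_a n_a! 2^H / ( (2n)! Π_{i<=j} c_ij! )

The two-sided exact p-value is the total probability of tables no more
probable than the observed one. Choices:

* All probabilities are computed in log space via `gammaln`, so cohorts
  of hundreds of individuals cannot overflow.
* The tie rule `P(t') <= P(t)` is applied with relative tolerance 1e-12
  (log-space slack `log1p(1e-12)`), a floating-point-safe definition of
  the tail.
* Enumeration fills the upper-triangular genotype count matrix cell by
  cell with branch pruning, and is used while the table count stays
  under 10^6 (`method="auto"`); the enumerated tail is normalised by the
  enumerated total, so a monomorphic locus yields exactly p = 1.
* Monte-Carlo: each null draw is one random pairing of the 2n-copy
  multiset (a row-wise permutation, paired off consecutively), which
  samples Levene's distribution exactly; the estimator is
  (1 + #{P(t') <= P(t)}) / (S + 1), including the observed table so the
  estimate remains a valid p-value. Sampling is vectorised and chunked
  to bound memory; fewer than 1,000 samples are refused as unstable. A
  seed is mandatory and recorded in the result.

A simple Guo–Thompson-style Markov chain was deliberately not
implemented; independent resampling is exact and fast at these sizes.

## EM haplotype frequency estimation

For individuals typed at all requested loci, the candidate haplotype
set is the union of phase-compatible haplotypes of the sample (the full
allele cross-product adds zero-probability candidates only). An
individual heterozygous at k loci has max(1, 2^(k-1)) unordered
phase-consistent pairs (capped at 4,096 per individual). The
observed-data likelihood per individual is Σ_pairs (2−δ_ij) h_i h_j;
EM alternates responsibility-weighted pair counts (E) with frequency
updates h = expected copies / 2N (M). Numerics:

* Convergence: log-likelihood gain < 1e-9 or 1,000 iterations; both are
  recorded, and an optional trace verifies monotone ascent.
* Initialisation: uniform over candidates times U(0.95, 1.05)
  multiplicative jitter, re-normalised, per restart (default 5; seeded).
  The exactly uniform start can be a symmetric fixed point — a single
  double-heterozygote stays at (¼,¼,¼,¼) with genotype probability
  0.25 instead of reaching a two-haplotype solution with probability
  0.5 — and jitter breaks that symmetry; the best-likelihood restart is
  returned.
* Frequencies below 1e-7 are pruned after convergence (numerical dust)
  and the remainder renormalised.

A consequence of the M-step is that estimated two-locus marginals equal
the single-locus direct-count frequencies to machine precision; the
tests assert this conservation.

## Linkage disequilibrium

For allele pair (i, j): D_ij = p_ij − p_i q_j, normalised by
D_max = min(p_i(1−q_j), (1−p_i)q_j) for positive D and
min(p_i q_j, (1−p_i)(1−q_j)) for negative D (Lewontin). The single
locus-pair summary is Hedrick's frequency-weighted mean
D′ = Σ_ij p_i q_j |D′_ij| — the convention used by the population
genetics software this pipeline mirrors — with the Cramér's-V analogue
W_n = sqrt(Σ D²/(p_i q_j) / min(k_A−1, k_B−1)) as a second summary.
Fixed or absent margins make a pair degenerate (D′ = 0, flagged);
a monomorphic locus yields a degenerate summary with D′ = 0. LD is
computed from EM-estimated haplotype frequencies when given a cohort,
mirroring the estimate-then-summarise pipeline order.

## Haplotype networks

Edges connect alleles at two different loci that co-occur on a
haplotype. Styling is a pure function of frequency and thresholds, with
strict `>` comparisons: with a display threshold only haplotypes above
it are drawn; with a bold threshold (display threshold 0) every
haplotype is drawn, bold above and dotted below. Multiple sources
(e.g. several cohorts or repositories) contribute parallel edges tagged
by source label — never averaged. DOT output sorts nodes and edges
lexicographically so identical graphs serialise byte-identically; the
emitter is hand-written because DOT is a trivial line format and
determinism is part of the contract.

## Binding profiles and distance trees

Peptides are length-k substrings drawn uniformly over all (protein,
start) windows with replacement; windows containing non-standard
residues are rejected and redrawn. Class I conventionally uses k = 9,
class II k = 15. Affinity scores live in [0, 1] with ≥0.4 labelled weak
and ≥0.6 strong binders. Allele similarity is the Pearson correlation
of raw score profiles (no rank or log transform), distance 1 − r;
a zero-variance profile has correlation defined as 0 (distance 1,
warned), and sub-1e-12 distances are snapped to exactly 0 so identical
profiles are at distance zero rather than rounding dust. DQA1 is
excluded from tree analyses by default (its binding is only defined
with a DQB1 partner); a control-set helper picks the top-m most
frequent alleles at a locus excluding a user-given test set.

Neighbor joining is the classic Saitou–Nei algorithm with the
Q-criterion; ties in Q (within 1e-12) break on the lexicographically
smallest cluster-label pair, so output is deterministic. Negative
branch-length estimates on non-additive input are clamped to 0 with the
deficit logged. Two taxa produce a midpoint-split single edge. Newick
output roots at the internal node adjacent to the smallest leaf, orders
children by smallest descendant leaf, and single-quotes labels
containing metacharacters (HLA names always do); PHYLIP square distance
output pads labels to 10 characters. On additive matrices the tree's
path metric reproduces the input to ~1e-15, verified against randomly
generated trees and cross-checked against scikit-bio's independent NJ.

## Synthetic generators

The simulator emulates the *structure* of a typed cohort, not any real
population: haplotype spectra are (1−λ)·product-of-marginals +
λ·bijective pairing (equifrequent marginals by default, explicit
marginals supported), so λ dials the frequency-weighted D′ continuously
from 0 to 1 — with equifrequent alleles, D′ equals λ exactly. Cohorts
are drawn by random union of haplotypes; with probability f the second
haplotype is a copy of the first. This whole-genotype copying is a test
device producing simultaneous homozygosity excess at every locus, not a
demographic model. Passing tests therefore demonstrate correctness of
the estimators under their own sampling assumptions (random mating,
no genotyping error, no ambiguity structure), not robustness to real
typing artefacts.

The surrogate scorer mimics motif-based prediction: each allele owns a
k×20 position weight matrix, scores are per-position sums squashed to
[0, 1] by min-max limits frozen over a seeded reference peptide sample
(deterministic given allele and peptide). Group base matrices are drawn
centred per position and mutually orthogonalised: under a near-uniform
residue distribution the score covariance of two matrices is
proportional to their inner product, so unrelated motif groups have
population profile correlation ≈ 0 rather than the O(1/√(20k)) leakage
independent draws would give, while `noise_sd` dials within-group
similarity. The surrogate reproduces the *geometry* of motif scoring
(shared motifs ⇒ correlated profiles ⇒ joint clades), not any real
allele's specificity.

## Study sizes used in validation

The acceptance script and test suite use: 1,000 replicate cohorts of
n = 100 at a 5-allele locus for the type-I error of the exact test
(Monte-Carlo, 2,000 samples each); 100 replicates of n = 500 with
f = 0.5 for power; 20 cohorts of n = 500 from a 6-haplotype two-locus
spectrum for EM recovery; and random additive matrices of 5–8 taxa for
NJ. These sizes give stable rates in seconds on one core while staying
in the regime the estimators are designed for.

## Known limitations

* The exact test's Monte-Carlo path estimates the tail, so p-values
  carry O(1/√S) noise; enumeration is exact but capped at 10^6 tables.
* EM returns a single maximum-likelihood spectrum; no per-individual
  phase posteriors, no partition-ligation for many loci, and the usual
  EM caveat that multimodal likelihoods are only explored via restarts.
* Which multiallelic D′ pooling convention a given published value used
  is not always stated; this package implements the frequency-weighted
  |D′| convention and reports W_n alongside.
* The surrogate scorer is not a trained predictor; real binding-profile
  trees require external predictor output, which can be supplied as a
  profile TSV to the `bindtree` stage.
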