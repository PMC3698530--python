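"""Peptide binding-profile distance trees.

Six alleles in two motif groups score 2,000 random 9-mer peptides with a
surrogate motif scorer; allele similarity is the Pearson correlation of
score profiles, distance is 1 - r, and the neighbor-joining tree should
cluster each motif group together.
"""

import numpy as np

from hlapop import (
    classify_binder,
    correlation_distance_matrix,
    make_surrogate_scorer,
    neighbor_joining,
    phylip_distance_text,
    sample_peptides,
    score_profiles,
    to_newick,
)

alleles = ["B*57:01", "B*58:01", "B*57:03", "A*02:01", "A*02:05", "A*02:06"]
groups = {a: 0 if a.startswith("B") else 1 for a in alleles}
scorer = make_surrogate_scorer(alleles, k=9, motif_groups=groups,
                               noise_sd=0.4, seed=3)

rng = np.random.default_rng(3)
proteome = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2000))]
peptides = sample_peptides(proteome, k=9, n=2000, seed=3)

profile = score_profiles(alleles, peptides, scorer)
first = profile.scores[0, 0]
print(f"score({alleles[0]}, {peptides.peptides[0]}) = {first:.3f} "
      f"-> {classify_binder(first)}")

d = correlation_distance_matrix(profile)
print("\nPHYLIP distance matrix:")
print(phylip_distance_text(d))
print("NJ tree:")
print(to_newick(neighbor_joining(d)))
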