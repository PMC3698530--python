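import numpy as np
import pytest

from hlapop.errors import InputError
from hlapop.frequencies import allele_frequencies
from hlapop.haplotypes import em_haplotype_frequencies
from hlapop.ld import pairwise_ld
from hlapop.njtree import neighbor_joining
from hlapop.binding import correlation_distance_matrix, sample_peptides, score_profiles
from hlapop.simulate import (
    SimulationConfig,
    make_haplotype_spectrum,
    make_surrogate_scorer,
    simulate_cohort,
    synthetic_allele,
)


class TestSpectrum:
    def test_frequencies_sum_to_one(self):
        for lam in (0.0, 0.3, 1.0):
            cfg = SimulationConfig(
                loci=("A", "B"), alleles_per_locus=(4, 4), ld_weight=lam
            )
            s = make_haplotype_spectrum(cfg)
            assert sum(s.freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_product_spectrum_has_full_support(self):
        cfg = SimulationConfig(loci=("A", "B"), alleles_per_locus=(3, 4))
        assert len(make_haplotype_spectrum(cfg).freqs) == 12

    def test_bijective_spectrum_is_diagonal(self):
        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(5, 5), ld_weight=1.0
        )
        s = make_haplotype_spectrum(cfg)
        assert len(s.freqs) == 5
        for h in s.freqs:
            assert h[0].fields == h[1].fields

    def test_unequal_counts_with_ld_rejected(self):
        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(3, 4), ld_weight=0.5
        )
        with pytest.raises(InputError, match="equal allele counts"):
            make_haplotype_spectrum(cfg)

    def test_explicit_marginals(self):
        cfg = SimulationConfig(
            loci=("A",), alleles_per_locus=(3,),
            marginals=((0.5, 0.3, 0.2),),
        )
        s = make_haplotype_spectrum(cfg)
        marg = {h[0].name: f for h, f in s.freqs.items()}
        assert marg[synthetic_allele("A", 0).name] == pytest.approx(0.5)

    def test_invalid_config_rejected(self):
        with pytest.raises(InputError):
            SimulationConfig(loci=("A",), alleles_per_locus=(3,), ld_weight=1.5)
        with pytest.raises(InputError):
            SimulationConfig(loci=("A",), alleles_per_locus=(3,), n=0)


class TestCohortSimulation:
    def test_full_inbreeding_is_all_homozygous(self):
        cfg = SimulationConfig(loci=("A", "B"), alleles_per_locus=(4, 4))
        cohort = simulate_cohort(
            make_haplotype_spectrum(cfg), n=50, f=1.0, seed=1
        )
        for r in cohort.records:
            for locus in ("A", "B"):
                assert r.is_homozygous(locus)

    def test_same_seed_identical_cohort(self):
        cfg = SimulationConfig(loci=("A",), alleles_per_locus=(5,))
        s = make_haplotype_spectrum(cfg)
        c1 = simulate_cohort(s, n=100, seed=9)
        c2 = simulate_cohort(s, n=100, seed=9)
        assert [r.genotype for r in c1.records] == [
            r.genotype for r in c2.records
        ]
        c3 = simulate_cohort(s, n=100, seed=10)
        assert [r.genotype for r in c1.records] != [
            r.genotype for r in c3.records
        ]

    def test_marginal_recovery_large_cohort(self):
        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(4, 4), ld_weight=0.4
        )
        spectrum = make_haplotype_spectrum(cfg)
        cohort = simulate_cohort(spectrum, n=2000, seed=13)
        for locus in ("A", "B"):
            t = allele_frequencies(cohort, locus)
            for allele, true_f in spectrum.marginal(locus).items():
                assert abs(t.af(allele.name) - true_f) < 0.03

    def test_end_to_end_ld_recovery(self):
        """Simulate -> EM -> D' recovers the generating spectrum's LD."""
        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(3, 3), ld_weight=0.7
        )
        spectrum = make_haplotype_spectrum(cfg)
        true_dprime = pairwise_ld(spectrum, "A", "B").overall_dprime
        cohort = simulate_cohort(spectrum, n=500, seed=21)
        est = em_haplotype_frequencies(cohort, ("A", "B"), seed=21)
        err = max(
            abs(est.freqs.get(h, 0.0) - f) for h, f in spectrum.freqs.items()
        )
        assert err < 0.03
        est_dprime = pairwise_ld(est, "A", "B").overall_dprime
        assert abs(est_dprime - true_dprime) < 0.05


class TestSurrogateScorer:
    def test_zero_noise_same_group_identical_profiles(self):
        scorer = make_surrogate_scorer(
            ["x", "y"], k=9, motif_groups={"x": 0, "y": 0},
            noise_sd=0.0, seed=3,
        )
        peps = sample_peptides(
            ["".join(np.random.default_rng(3).choice(
                list("ACDEFGHIKLMNPQRSTVWY"), size=200))],
            k=9, n=300, seed=3,
        )
        profile = score_profiles(["x", "y"], peps, scorer)
        assert np.allclose(profile.scores[0], profile.scores[1])
        d = correlation_distance_matrix(profile)
        assert d.get("x", "y") == pytest.approx(0.0, abs=1e-12)

    def test_scores_in_unit_interval(self):
        scorer = make_surrogate_scorer(["x"], k=9, noise_sd=0.5, seed=4)
        rng = np.random.default_rng(4)
        peps = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=9))
            for _ in range(5000)
        ]
        scores = scorer.score_many("x", peps)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_different_groups_nearly_uncorrelated(self):
        scorer = make_surrogate_scorer(
            ["x", "y"], k=9, motif_groups={"x": 0, "y": 1},
            noise_sd=0.0, seed=6,
        )
        rng = np.random.default_rng(6)
        prot = ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=2000))]
        peps = sample_peptides(prot, k=9, n=10_000, seed=6)
        profile = score_profiles(["x", "y"], peps, scorer)
        assert abs(np.corrcoef(profile.scores)[0, 1]) < 0.1

    def test_deterministic_given_allele_and_peptide(self):
        scorer = make_surrogate_scorer(["x"], k=9, noise_sd=0.3, seed=8)
        assert scorer("x", "ACDEFGHIK") == scorer("x", "ACDEFGHIK")

    def test_negative_noise_rejected(self):
        with pytest.raises(InputError):
            make_surrogate_scorer(["x"], k=9, noise_sd=-0.1, seed=0)

    def test_group_structure_yields_monophyletic_clades(self):
        """Same-group alleles cluster together in the NJ tree."""
        alleles = ["a1", "a2", "a3", "b1", "b2", "b3"]
        groups = {a: 0 if a.startswith("a") else 1 for a in alleles}
        successes = 0
        n_rep = 10
        for seed in range(n_rep):
            scorer = make_surrogate_scorer(
                alleles, k=9, motif_groups=groups, noise_sd=0.5,
                seed=seed,
            )
            rng = np.random.default_rng(seed)
            prot = [
                "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=1500))
            ]
            peps = sample_peptides(prot, k=9, n=1500, seed=seed)
            profile = score_profiles(alleles, peps, scorer)
            tree = neighbor_joining(correlation_distance_matrix(profile))
            # the two groups are separated by some edge iff removing one
            # edge splits leaves exactly into the group bipartition
            target = frozenset(["a1", "a2", "a3"])
            found = False
            import networkx as nx

            for u, v in list(tree.graph.edges):
                g = tree.graph.copy()
                g.remove_edge(u, v)
                side = {
                    n for n in nx.node_connected_component(g, u)
                    if not str(n).startswith("_nj")
                }
                if side == target or (set(alleles) - side) == target:
                    found = True
                    break
            successes += found
        assert successes >= n_rep - 1
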