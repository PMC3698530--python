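"""EM haplotype estimation: phase expansion, likelihood, and oracles.

The small-case oracle is direct maximisation of the observed-data
likelihood over a fine grid on the frequency simplex, independent of the
EM code path.
"""

import itertools
import math

import numpy as np
import pytest

from conftest import make_cohort
from hlapop.errors import InputError
from hlapop.haplotypes import (
    HaplotypeFrequencySpectrum,
    em_haplotype_frequencies,
    haplotype_name,
    log_likelihood,
    phase_expansions,
    write_haplotype_table,
)
from hlapop.nomenclature import parse_allele
from hlapop.simulate import (
    SimulationConfig,
    make_haplotype_spectrum,
    simulate_cohort,
)


def hap(*names):
    return tuple(parse_allele(n) for n in names)


class TestPhaseExpansions:
    def test_fully_homozygous_has_single_pair(self):
        c = make_cohort(
            {"s": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*07:02")}}
        )
        pairs = phase_expansions(c.records[0], ("A", "B"))
        assert pairs == [
            (hap("A*01:01", "B*07:02"), hap("A*01:01", "B*07:02"))
        ]

    def test_double_heterozygote_has_two_pairs(self):
        c = make_cohort(
            {"s": {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01")}}
        )
        pairs = phase_expansions(c.records[0], ("A", "B"))
        assert len(pairs) == 2
        assert set(pairs) == {
            (hap("A*01:01", "B*07:02"), hap("A*02:01", "B*08:01")),
            (hap("A*01:01", "B*08:01"), hap("A*02:01", "B*07:02")),
        }

    @pytest.mark.parametrize("n_het", [1, 2, 3, 4])
    def test_expansion_count_matches_brute_force(self, n_het):
        """2^(k-1) unordered pairs, verified by collapsing all 2^k ordered
        phasings to unordered pairs."""
        loci = ("A", "B", "C", "DRB1")[:n_het]
        geno = {
            locus: (f"{locus}*01:01", f"{locus}*02:01") for locus in loci
        }
        c = make_cohort({"s": geno})
        pairs = phase_expansions(c.records[0], loci)
        assert len(pairs) == max(1, 2 ** (n_het - 1))

        # brute force: all orientations of every heterozygous locus
        parsed = {l: tuple(map(parse_allele, g)) for l, g in geno.items()}
        brute = set()
        for flips in itertools.product((0, 1), repeat=n_het):
            h1 = tuple(parsed[l][f] for l, f in zip(loci, flips))
            h2 = tuple(parsed[l][1 - f] for l, f in zip(loci, flips))
            brute.add((h1, h2) if h1 <= h2 else (h2, h1))
        assert set(pairs) == brute

    def test_expansion_cap_enforced(self):
        loci = ("A", "B", "C", "DRB1", "DQB1")
        geno = {l: (f"{l}*01:01", f"{l}*02:01") for l in loci}
        c = make_cohort({"s": geno})
        with pytest.raises(InputError, match="cap"):
            phase_expansions(c.records[0], loci, cap=8)


class TestLogLikelihood:
    def test_single_homozygote_is_zero(self):
        c = make_cohort(
            {"s": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*07:02")}}
        )
        spectrum = HaplotypeFrequencySpectrum(
            loci=("A", "B"), freqs={hap("A*01:01", "B*07:02"): 1.0}
        )
        assert log_likelihood(spectrum, c) == pytest.approx(0.0)

    def test_double_het_uniform_spectrum(self):
        c = make_cohort(
            {"s": {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01")}}
        )
        freqs = {
            hap(a, b): 0.25
            for a in ("A*01:01", "A*02:01")
            for b in ("B*07:02", "B*08:01")
        }
        spectrum = HaplotypeFrequencySpectrum(loci=("A", "B"), freqs=freqs)
        # two compatible unordered pairs, each with probability 2*0.25*0.25
        assert log_likelihood(spectrum, c) == pytest.approx(math.log(0.25))

    def test_unsupported_individual_gives_minus_inf(self):
        c = make_cohort(
            {"s": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*07:02")}}
        )
        spectrum = HaplotypeFrequencySpectrum(
            loci=("A", "B"), freqs={hap("A*02:01", "B*08:01"): 1.0}
        )
        with pytest.warns(UserWarning, match="s"):
            assert log_likelihood(spectrum, c) == float("-inf")


class TestEM:
    def test_forced_phase_hand_count(self, two_locus_cohort):
        s = em_haplotype_frequencies(two_locus_cohort, ("A", "B"), seed=0)
        freqs = {haplotype_name(h): f for h, f in s.freqs.items()}
        assert freqs["A*01:01~B*07:02"] == pytest.approx(0.5, abs=1e-9)
        assert freqs["A*01:01~B*08:01"] == pytest.approx(0.25, abs=1e-9)
        assert freqs["A*02:01~B*07:02"] == pytest.approx(0.25, abs=1e-9)
        assert s.converged

    def test_all_homozygous_equals_direct_counting(self):
        c = make_cohort(
            {
                "s1": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*07:02")},
                "s2": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*07:02")},
                "s3": {"A": ("A*02:01", "A*02:01"), "B": ("B*08:01", "B*08:01")},
            }
        )
        s = em_haplotype_frequencies(c, ("A", "B"), seed=0)
        freqs = {haplotype_name(h): f for h, f in s.freqs.items()}
        assert freqs == pytest.approx(
            {"A*01:01~B*07:02": 2 / 3, "A*02:01~B*08:01": 1 / 3}
        )

    def test_single_double_het_escapes_symmetric_fixed_point(self):
        """Uniform start is a saddle (genotype probability 0.25); jittered
        restarts reach a two-haplotype optimum (probability 0.5)."""
        c = make_cohort(
            {"s": {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*08:01")}}
        )
        s = em_haplotype_frequencies(c, ("A", "B"), seed=3)
        assert math.exp(s.log_likelihood) == pytest.approx(0.5, abs=1e-6)
        assert sorted(s.freqs.values()) == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_monotone_log_likelihood_trace(self):
        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(4, 4), ld_weight=0.5,
            n=100, seed=2,
        )
        cohort = simulate_cohort(make_haplotype_spectrum(cfg), n=100, seed=2)
        s = em_haplotype_frequencies(
            cohort, ("A", "B"), seed=2, keep_trace=True
        )
        trace = np.array(s.ll_trace)
        assert len(trace) >= 2
        assert (np.diff(trace) >= -1e-9).all()

    def test_em_likelihood_not_below_initialisation(self, two_locus_cohort):
        s = em_haplotype_frequencies(two_locus_cohort, ("A", "B"), seed=0)
        uniform = HaplotypeFrequencySpectrum(
            loci=("A", "B"),
            freqs={
                h: 1 / 4
                for h in [
                    hap("A*01:01", "B*07:02"), hap("A*01:01", "B*08:01"),
                    hap("A*02:01", "B*07:02"), hap("A*02:01", "B*08:01"),
                ]
            },
        )
        assert s.log_likelihood >= log_likelihood(uniform, two_locus_cohort)

    def test_grid_search_oracle_small_cohort(self, two_locus_cohort):
        """EM matches brute-force likelihood maximisation on a 0.001-step
        simplex grid for a 3-haplotype cohort."""
        s = em_haplotype_frequencies(two_locus_cohort, ("A", "B"), seed=0)
        h1 = hap("A*01:01", "B*07:02")
        h2 = hap("A*01:01", "B*08:01")
        h3 = hap("A*02:01", "B*07:02")
        best, best_ll = None, -np.inf
        steps = np.arange(0, 1.0001, 0.001)
        for f1 in steps:
            rest = 1.0 - f1
            f2s = np.arange(0, rest + 1e-12, 0.001)
            f3s = rest - f2s
            # individual 1: 2*h1*h2 ; individual 2: 2*h1*h3
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.log(2 * f1 * f2s) + np.log(2 * f1 * f3s)
            i = int(np.argmax(ll))
            if ll[i] > best_ll:
                best_ll, best = ll[i], (f1, f2s[i], f3s[i])
        assert s.log_likelihood >= best_ll - 1e-9
        est = [s.freqs.get(h, 0.0) for h in (h1, h2, h3)]
        assert np.allclose(est, best, atol=0.01)

    def test_marginals_match_direct_counts(self):
        """M-step conservation: 2-locus EM marginals equal single-locus
        direct-count allele frequencies."""
        from hlapop.frequencies import allele_frequencies

        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(4, 4), ld_weight=0.3,
            n=150, seed=9,
        )
        cohort = simulate_cohort(make_haplotype_spectrum(cfg), n=150, seed=9)
        s = em_haplotype_frequencies(cohort, ("A", "B"), seed=9)
        for locus in ("A", "B"):
            direct = allele_frequencies(cohort, locus)
            marg = {a.name: f for a, f in s.marginal(locus).items()}
            for allele in direct.alleles:
                assert marg.get(allele, 0.0) == pytest.approx(
                    direct.af(allele), abs=1e-6
                )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parameter_recovery(self, seed):
        cfg = SimulationConfig(
            loci=("A", "B"), alleles_per_locus=(3, 3), ld_weight=0.6,
            n=500, seed=seed,
        )
        spectrum = make_haplotype_spectrum(cfg)
        assert len(spectrum.freqs) >= 6
        cohort = simulate_cohort(spectrum, n=500, seed=seed)
        est = em_haplotype_frequencies(cohort, ("A", "B"), seed=seed)
        err = max(
            abs(est.freqs.get(h, 0.0) - f) for h, f in spectrum.freqs.items()
        )
        assert err < 0.03

    def test_untyped_individuals_are_excluded(self):
        c = make_cohort(
            {
                "s1": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*07:02")},
                "s2": {"A": ("A*02:01", "A*02:01")},
            }
        )
        s = em_haplotype_frequencies(c, ("A", "B"), seed=0)
        assert haplotype_name(next(iter(s.freqs))) == "A*01:01~B*07:02"

    def test_no_usable_individual_raises(self):
        c = make_cohort({"s1": {"A": ("A*01:01", "A*01:01")}})
        with pytest.raises(InputError):
            em_haplotype_frequencies(c, ("A", "B"), seed=0)


def test_haplotype_table_output(tmp_path, two_locus_cohort):
    s = em_haplotype_frequencies(two_locus_cohort, ("A", "B"), seed=0)
    p = tmp_path / "hap.tsv"
    write_haplotype_table(s, p)
    lines = p.read_text().splitlines()
    assert lines[0] == "haplotype\tfrequency"
    assert lines[1] == "A*01:01~B*07:02\t0.500"
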