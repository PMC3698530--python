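"""Synthetic study inputs: haplotype spectra with controlled LD, diploid
cohorts under Hardy-Weinberg random union of haplotypes, and a
motif-based surrogate binding scorer.

These generators emulate the structure of an HLA-typed cohort — not any
particular population's allele spectrum. The LD dial interpolates
linearly between a product-of-marginals spectrum (no LD) and a bijective
allele pairing (complete LD); the inbreeding coefficient ``f`` copies an
individual's first haplotype with probability ``f``, a simple device that
produces homozygosity excess at every locus simultaneously. The surrogate
scorer mimics motif-based binding prediction: each allele scores peptides
through a position weight matrix, with alleles in the same motif group
sharing a base matrix plus independent noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .binding import STANDARD_AA
from .cohort import Cohort, GenotypeRecord
from .errors import InputError
from .haplotypes import (
    Haplotype,
    HaplotypeFrequencySpectrum,
    haplotype_name,
)
from .nomenclature import Allele


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation parameters, recorded in output provenance.

    ``ld_weight`` interpolates between independence (0) and a bijective
    allele pairing across loci (1); ``inbreeding`` is the probability an
    individual's two haplotypes are identical copies.
    """

    loci: tuple[str, ...]
    alleles_per_locus: tuple[int, ...]
    ld_weight: float = 0.0
    n: int = 100
    inbreeding: float = 0.0
    seed: int = 0
    marginals: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_weight <= 1.0:
            raise InputError(f"ld_weight must be in [0, 1], got {self.ld_weight}")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise InputError(f"inbreeding must be in [0, 1], got {self.inbreeding}")
        if self.n < 1:
            raise InputError(f"n must be >= 1, got {self.n}")
        if len(self.loci) != len(self.alleles_per_locus):
            raise InputError("loci and alleles_per_locus length mismatch")

    def to_dict(self) -> dict:
        return {
            "loci": list(self.loci),
            "alleles_per_locus": list(self.alleles_per_locus),
            "ld_weight": self.ld_weight,
            "n": self.n,
            "inbreeding": self.inbreeding,
            "seed": self.seed,
            "marginals": None if self.marginals is None
            else [list(m) for m in self.marginals],
        }


def synthetic_allele(locus: str, index: int) -> Allele:
    """Deterministic synthetic allele label, e.g. the 3rd A allele A*03:01."""
    return Allele(locus, (f"{index + 1:02d}", "01"))


def make_haplotype_spectrum(config: SimulationConfig) -> HaplotypeFrequencySpectrum:
    """Spectrum = (1-λ)·product-of-marginals + λ·bijective pairing.

    Marginals default to equifrequent alleles at every locus; explicit
    per-locus marginals may be supplied in the config. The bijective
    component pairs the i-th allele at every locus and carries the first
    locus's marginal mass, so it requires equal allele counts across loci.
    """
    lam = config.ld_weight
    counts = config.alleles_per_locus
    if config.marginals is not None:
        marginals = [np.asarray(m, dtype=float) for m in config.marginals]
        for m, c in zip(marginals, counts):
            if len(m) != c or abs(m.sum() - 1.0) > 1e-9 or (m < 0).any():
                raise InputError("invalid explicit marginals")
    else:
        marginals = [np.full(c, 1.0 / c) for c in counts]
    if lam > 0.0 and len(set(counts)) != 1:
        raise InputError(
            "bijective LD component requires equal allele counts across loci"
        )

    alleles = [
        [synthetic_allele(locus, i) for i in range(c)]
        for locus, c in zip(config.loci, counts)
    ]
    freqs: dict[Haplotype, float] = {}

    def add(hap: Haplotype, f: float) -> None:
        if f > 0.0:
            freqs[hap] = freqs.get(hap, 0.0) + f

    # product component
    if lam < 1.0:
        grids = np.meshgrid(*[np.arange(c) for c in counts], indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)
        for row in idx:
            f = (1.0 - lam) * float(
                np.prod([marginals[l][i] for l, i in enumerate(row)])
            )
            add(tuple(alleles[l][i] for l, i in enumerate(row)), f)
    # bijective component, mass from the first locus's marginal
    if lam > 0.0:
        for i in range(counts[0]):
            add(
                tuple(alleles[l][i] for l in range(len(counts))),
                lam * float(marginals[0][i]),
            )
    total = sum(freqs.values())
    freqs = {h: f / total for h, f in freqs.items()}
    return HaplotypeFrequencySpectrum(loci=config.loci, freqs=freqs)


def simulate_cohort(
    spectrum: HaplotypeFrequencySpectrum,
    n: int,
    f: float = 0.0,
    seed: int = 0,
    population: str = "SIM",
    ethnicity: str = "synthetic",
) -> Cohort:
    """Draw a diploid cohort by random union of haplotypes.

    Each individual draws two haplotypes i.i.d. from the spectrum; with
    probability ``f`` the second is a copy of the first. Genotypes are
    stored unphased (allele pairs normalised per locus).
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if not 0.0 <= f <= 1.0:
        raise InputError(f"inbreeding coefficient must be in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    haps = list(spectrum.freqs)
    probs = np.array([spectrum.freqs[h] for h in haps])
    probs = probs / probs.sum()
    first = rng.choice(len(haps), size=n, p=probs)
    second = rng.choice(len(haps), size=n, p=probs)
    copy_mask = rng.random(n) < f
    second = np.where(copy_mask, first, second)

    width = len(str(n))
    records = []
    for i in range(n):
        h1, h2 = haps[first[i]], haps[second[i]]
        genotype = {
            locus: (h1[li], h2[li])
            for li, locus in enumerate(spectrum.loci)
        }
        records.append(
            GenotypeRecord(
                sample_id=f"S{i + 1:0{width}d}",
                population=population,
                ethnicity=ethnicity,
                genotype=genotype,
            )
        )
    return Cohort(records=tuple(records), loci=spectrum.loci)


def write_spectrum_json(spectrum: HaplotypeFrequencySpectrum, path) -> None:
    """Sidecar JSON of the true spectrum, for recovery experiments."""
    payload = {
        "loci": list(spectrum.loci),
        "freqs": {haplotype_name(h): f for h, f in spectrum.freqs.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class SurrogateScorer:
    """Motif-based stand-in for a trained peptide-binding predictor.

    Each allele owns a k × 20 position weight matrix; a peptide's raw
    score is the sum of per-position weights, squashed to [0, 1] by
    min-max limits fixed at build time over a reference peptide sample
    (so scoring is deterministic given (allele, peptide)). Alleles in the
    same motif group share a base matrix plus independent N(0, noise_sd)
    perturbations, which dials their profile correlation.
    """

    k: int
    pwm: dict[str, np.ndarray] = field(repr=False)
    lo: dict[str, float] = field(repr=False)
    hi: dict[str, float] = field(repr=False)
    groups: dict[str, int] = field(repr=False)
    noise_sd: float = 0.0
    seed: int | None = None

    def __call__(self, allele: str, peptide: str) -> float:
        return float(self.score_many(allele, (peptide,))[0])

    def score_many(self, allele: str, peptides) -> np.ndarray:
        if allele not in self.pwm:
            raise InputError(f"scorer has no matrix for allele {allele}")
        m = self.pwm[allele]
        idx = np.array(
            [[STANDARD_AA.index(aa) for aa in p] for p in peptides]
        )
        if idx.shape[1] != self.k:
            raise InputError(
                f"peptides must have length {self.k}, got {idx.shape[1]}"
            )
        raw = m[np.arange(self.k), idx].sum(axis=1)
        lo, hi = self.lo[allele], self.hi[allele]
        span = hi - lo if hi > lo else 1.0
        return np.clip((raw - lo) / span, 0.0, 1.0)


def make_surrogate_scorer(
    alleles,
    k: int,
    motif_groups: dict[str, int] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_reference_peptides: int = 512,
) -> SurrogateScorer:
    """Build a surrogate scorer for the given allele names.

    ``motif_groups`` assigns each allele to a shared-motif group (default:
    every allele its own group). ``noise_sd`` scales each allele's private
    deviation from its group's base matrix.
    """
    alleles = [str(a) for a in alleles]
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    if motif_groups is None:
        motif_groups = {a: i for i, a in enumerate(alleles)}
    for a in alleles:
        if a not in motif_groups:
            raise InputError(f"allele {a} missing from motif_groups")

    rng = np.random.default_rng(seed)
    # Group base motifs are drawn centred per position and mutually
    # orthogonal: under a (near-)uniform residue distribution the score
    # covariance of two matrices is proportional to their inner product,
    # so unrelated motif groups get population profile correlation ~0
    # instead of the O(1/sqrt(20k)) leakage of independent draws.
    group_ids = sorted(set(motif_groups[a] for a in alleles))
    if len(group_ids) > k * 19:
        raise InputError(
            f"at most {k * 19} orthogonal motif groups possible for k={k}"
        )
    base: dict[int, np.ndarray] = {}
    chosen: list[np.ndarray] = []
    for g in group_ids:
        m = rng.normal(0.0, 1.0, size=(k, 20))
        m -= m.mean(axis=1, keepdims=True)
        v = m.ravel()
        norm0 = np.linalg.norm(v)
        for w in chosen:
            v = v - (v @ w) * w
        v /= np.linalg.norm(v)
        chosen.append(v)
        base[g] = (v * norm0).reshape(k, 20)
    pwm = {
        a: base[motif_groups[a]] + rng.normal(0.0, noise_sd, size=(k, 20))
        for a in alleles
    }
    # squash limits from a fixed reference sample of uniform-random peptides
    ref_idx = rng.integers(0, 20, size=(n_reference_peptides, k))
    lo, hi = {}, {}
    pos = np.arange(k)
    for a in alleles:
        raw = pwm[a][pos, ref_idx].sum(axis=1)
        lo[a], hi[a] = float(raw.min()), float(raw.max())
    return SurrogateScorer(
        k=k, pwm=pwm, lo=lo, hi=hi,
        groups=dict(motif_groups), noise_sd=noise_sd, seed=seed,
    )
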