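"""Maximum-likelihood haplotype frequency estimation via EM.

With unphased diploid genotypes at several loci, the haplotype pair an
individual carries is ambiguous whenever they are heterozygous at two or
more loci (2^(k-1) phase-consistent pairs for k heterozygous loci). The EM
algorithm iterates:

  E-step  weight each compatible pair (h_i, h_j) by (2 - δ_ij) h_i h_j,
          normalised per individual;
  M-step  set each haplotype frequency to its expected copy count / 2N.

The observed-data log-likelihood Σ_g log Σ_pairs (2-δ) h_i h_j is
non-decreasing across iterations; EM is restarted from jittered uniform
starts because the exactly-uniform start can sit on a symmetric saddle
(e.g. a single double-heterozygote, where uniform frequencies are a fixed
point with half the likelihood of the two-haplotype optimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np

from .cohort import Cohort, GenotypeRecord
from .errors import InputError, NumericalError
from .nomenclature import Allele

Haplotype = tuple[Allele, ...]

DEFAULT_TOL = 1e-9
DEFAULT_MAX_ITER = 1_000
DEFAULT_RESTARTS = 5
DEFAULT_EXPANSION_CAP = 4_096
PRUNE_THRESHOLD = 1e-7


def haplotype_name(h: Haplotype) -> str:
    """Conventional tilde-joined rendering, e.g. ``DRB1*07:01~DQB1*02:01g``."""
    return "~".join(a.name for a in h)


@dataclass(frozen=True)
class HaplotypeFrequencySpectrum:
    """Multilocus haplotype frequencies with EM fit metadata.

    ``freqs`` maps ordered allele tuples (one per locus in ``loci``) to
    frequencies summing to 1. For spectra constructed directly (e.g. by the
    simulator) the fit metadata is trivial.
    """

    loci: tuple[str, ...]
    freqs: dict[Haplotype, float]
    log_likelihood: float = float("nan")
    iterations: int = 0
    converged: bool = True
    n_restarts_used: int = 0
    seed: int | None = None
    ll_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")
        if any(v < 0 for v in self.freqs.values()):
            raise ValueError("negative haplotype frequency")
        for h in self.freqs:
            if len(h) != len(self.loci):
                raise ValueError(
                    f"haplotype arity {len(h)} != {len(self.loci)} loci"
                )
        object.__setattr__(self, "loci", tuple(self.loci))

    def marginal(self, locus: str) -> dict[Allele, float]:
        """Single-locus allele frequencies implied by the spectrum."""
        idx = self.loci.index(locus)
        out: dict[Allele, float] = {}
        for h, f in self.freqs.items():
            out[h[idx]] = out.get(h[idx], 0.0) + f
        return out

    def pair_marginal(
        self, locus_a: str, locus_b: str
    ) -> "HaplotypeFrequencySpectrum":
        """Collapse to the two-locus spectrum over (locus_a, locus_b)."""
        ia, ib = self.loci.index(locus_a), self.loci.index(locus_b)
        freqs: dict[Haplotype, float] = {}
        for h, f in self.freqs.items():
            key = (h[ia], h[ib])
            freqs[key] = freqs.get(key, 0.0) + f
        return HaplotypeFrequencySpectrum(
            loci=(locus_a, locus_b), freqs=freqs
        )


def phase_expansions(
    record: GenotypeRecord,
    loci: Sequence[str],
    cap: int = DEFAULT_EXPANSION_CAP,
) -> list[tuple[Haplotype, Haplotype]]:
    """All phase-consistent unordered haplotype pairs for one individual.

    For k heterozygous loci there are exactly max(1, 2^(k-1)) pairs: the
    orientation at the first heterozygous locus is fixed to avoid double
    counting mirror-image phasings.
    """
    for locus in loci:
        if not record.typed_at(locus):
            raise InputError(
                f"{record.sample_id} is untyped at {locus}; "
                "individuals must be typed at all analysis loci"
            )
    het = [
        locus for locus in loci if not record.is_homozygous(locus)
    ]
    n_pairs = max(1, 2 ** max(0, len(het) - 1))
    if n_pairs > cap:
        raise InputError(
            f"{record.sample_id}: {n_pairs} phase expansions exceed the "
            f"cap of {cap} ({len(het)} heterozygous loci)"
        )
    pairs: list[tuple[Haplotype, Haplotype]] = []
    first_het = het[0] if het else None
    for mask in range(n_pairs):
        h1: list[Allele] = []
        h2: list[Allele] = []
        bit = 0
        for locus in loci:
            a, b = record.genotype[locus]
            if a == b:
                h1.append(a)
                h2.append(a)
            elif locus == first_het:
                h1.append(a)
                h2.append(b)
            else:
                if (mask >> bit) & 1:
                    h1.append(b)
                    h2.append(a)
                else:
                    h1.append(a)
                    h2.append(b)
                bit += 1
        pair = (tuple(h1), tuple(h2))
        pairs.append(pair if pair[0] <= pair[1] else (pair[1], pair[0]))
    return pairs


def log_likelihood(
    spectrum: HaplotypeFrequencySpectrum,
    cohort: Cohort,
    loci: Sequence[str] | None = None,
) -> float:
    """Observed-data log-likelihood of a spectrum on a cohort.

    Haplotypes absent from the spectrum contribute zero probability; an
    individual with no supported phasing drives the result to -inf (a
    warning names the sample).
    """
    loci = tuple(loci) if loci is not None else spectrum.loci
    total = 0.0
    for r in cohort.records:
        if not all(r.typed_at(locus) for locus in loci):
            continue
        prob = 0.0
        for h1, h2 in phase_expansions(r, loci):
            f1 = spectrum.freqs.get(h1, 0.0)
            f2 = spectrum.freqs.get(h2, 0.0)
            prob += (1.0 if h1 == h2 else 2.0) * f1 * f2
        if prob <= 0.0:
            warnings.warn(
                f"sample {r.sample_id} has zero probability under the "
                "spectrum; log-likelihood is -inf",
                stacklevel=2,
            )
            return float("-inf")
        total += np.log(prob)
    return float(total)


def _em_single_run(
    pair_i: np.ndarray,
    pair_j: np.ndarray,
    pair_owner: np.ndarray,
    n_ind: int,
    n_hap: int,
    h0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    """One EM run from a given start; arrays index a flat pair list."""
    coef = np.where(pair_i == pair_j, 1.0, 2.0)
    h = h0.copy()
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = coef * h[pair_i] * h[pair_j]
        per_ind = np.bincount(pair_owner, weights=w, minlength=n_ind)
        if np.any(per_ind <= 0.0):
            raise NumericalError("individual with zero phase probability")
        ll = float(np.log(per_ind).sum())
        trace.append(ll)
        w = w / per_ind[pair_owner]
        copies = np.bincount(pair_i, weights=w, minlength=n_hap)
        copies += np.bincount(pair_j, weights=w, minlength=n_hap)
        h = copies / (2.0 * n_ind)
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
    # final log-likelihood at the returned frequencies
    w = coef * h[pair_i] * h[pair_j]
    per_ind = np.bincount(pair_owner, weights=w, minlength=n_ind)
    ll = float(np.log(per_ind).sum())
    trace.append(ll)
    return h, ll, it, converged, trace


def em_haplotype_frequencies(
    cohort: Cohort,
    loci: Sequence[str],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    keep_trace: bool = False,
) -> HaplotypeFrequencySpectrum:
    """EM estimate of haplotype frequencies over the given loci.

    Only individuals typed at every requested locus enter the analysis.
    The candidate haplotype set is the phase-compatible haplotypes of the
    sample (no likelihood is lost by excluding the rest). Each restart
    initialises uniformly over candidates with multiplicative U(0.95, 1.05)
    jitter; the best-likelihood restart is returned.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    loci = tuple(loci)
    usable = [
        r for r in cohort.records if all(r.typed_at(l) for l in loci)
    ]
    if not usable:
        raise InputError(
            f"no individual typed at all of {', '.join(loci)}"
        )

    hap_index: dict[Haplotype, int] = {}
    pair_i: list[int] = []
    pair_j: list[int] = []
    pair_owner: list[int] = []
    for owner, r in enumerate(usable):
        for h1, h2 in phase_expansions(r, loci):
            for h in (h1, h2):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            pair_i.append(hap_index[h1])
            pair_j.append(hap_index[h2])
            pair_owner.append(owner)

    n_hap = len(hap_index)
    n_ind = len(usable)
    pi = np.asarray(pair_i)
    pj = np.asarray(pair_j)
    po = np.asarray(pair_owner)

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, int, bool, list[float]] | None = None
    for _ in range(max(1, n_restarts)):
        h0 = np.full(n_hap, 1.0 / n_hap)
        h0 *= rng.uniform(0.95, 1.05, size=n_hap)
        h0 /= h0.sum()
        run = _em_single_run(pi, pj, po, n_ind, n_hap, h0, tol, max_iter)
        if best is None or run[1] > best[1]:
            best = run
    assert best is not None
    h, ll, iterations, converged, trace = best

    haps = list(hap_index)
    freqs = {
        haps[idx]: float(h[idx])
        for idx in range(n_hap)
        if h[idx] >= PRUNE_THRESHOLD
    }
    total = sum(freqs.values())
    freqs = {k: v / total for k, v in freqs.items()}
    return HaplotypeFrequencySpectrum(
        loci=loci,
        freqs=freqs,
        log_likelihood=ll,
        iterations=iterations,
        converged=converged,
        n_restarts_used=max(1, n_restarts),
        seed=seed,
        ll_trace=tuple(trace) if keep_trace else (),
    )


def write_haplotype_table(
    spectrum: HaplotypeFrequencySpectrum, path
) -> None:
    """TSV of haplotypes (alleles joined by ``~``) and 3-decimal frequencies."""
    rows = sorted(
        spectrum.freqs.items(), key=lambda kv: (-kv[1], haplotype_name(kv[0]))
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("haplotype\tfrequency\n")
        for h, f in rows:
            fh.write(f"{haplotype_name(h)}\t{f:.3f}\n")
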