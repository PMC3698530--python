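"""Exact test of Hardy-Weinberg proportions at a multiallelic locus.

The test conditions on the observed allele copy counts: under random
mating, Levene's distribution gives the probability of a genotype table
``t`` with heterozygote count ``H`` as

    P(t | n_a) = n! · Π_a n_a! · 2^H / [ (2n)! · Π_{i<=j} c_ij! ]

where ``c_ij`` are the genotype counts and ``n_a`` the allele copy counts.
The p-value is the total probability of tables no more probable than the
observed one — evaluated by complete enumeration when the table space is
small, otherwise by Monte-Carlo random pairing of the allele-copy multiset
(each shuffle-and-pair of the 2n copies is an exact draw from the null).

All probabilities are handled in log space via log-gamma so cohorts of
hundreds of individuals do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np
from scipy.special import gammaln, logsumexp

from .cohort import Cohort
from .errors import EnumerationCapError, InputError

_LOG2 = math.log(2.0)
#: Relative tolerance for the tie rule P(t') <= P(t) in floating point.
_TIE_RTOL = 1e-12
#: log-space slack equivalent to the relative tie tolerance.
_LOG_TIE = math.log1p(_TIE_RTOL)

DEFAULT_ENUMERATION_CAP = 1_000_000
DEFAULT_MC_SAMPLES = 100_000
_MC_CHUNK_ELEMENTS = 4_000_000  # bounds the shuffle matrix memory


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts at one locus: unordered allele pair -> individuals."""

    locus: str
    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        norm: dict[tuple[str, str], int] = {}
        for (a, b), c in self.counts.items():
            if c < 0:
                raise InputError(f"negative genotype count for ({a}, {b})")
            key = (a, b) if a <= b else (b, a)
            norm[key] = norm.get(key, 0) + c
        object.__setattr__(self, "counts", norm)

    @property
    def n(self) -> int:
        """Number of individuals."""
        return sum(self.counts.values())

    @property
    def allele_counts(self) -> dict[str, int]:
        """Allele copy counts n_a (sum = 2n); homozygotes count twice."""
        out: dict[str, int] = {}
        for (a, b), c in self.counts.items():
            if a == b:
                out[a] = out.get(a, 0) + 2 * c
            else:
                out[a] = out.get(a, 0) + c
                out[b] = out.get(b, 0) + c
        return out

    @property
    def heterozygote_count(self) -> int:
        return sum(c for (a, b), c in self.counts.items() if a != b)

    @classmethod
    def from_cohort(cls, cohort: Cohort, locus: str) -> "GenotypeCountTable":
        counts: dict[tuple[str, str], int] = {}
        for r in cohort.typed_records(locus):
            a, b = r.genotype[locus]
            key = (a.name, b.name)
            counts[key] = counts.get(key, 0) + 1
        if not counts:
            raise InputError(f"no individual typed at locus {locus}")
        return cls(locus=locus, counts=counts)


@dataclass(frozen=True)
class HWEResult:
    """Outcome of the exact Hardy-Weinberg test at one locus."""

    locus: str
    p_value: float
    method: Literal["enumeration", "monte_carlo"]
    observed_conditional_probability: float
    tables_enumerated: int | None = None
    mc_samples: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "locus": self.locus,
            "p_value": self.p_value,
            "method": self.method,
            "observed_conditional_probability":
                self.observed_conditional_probability,
            "tables_enumerated": self.tables_enumerated,
            "mc_samples": self.mc_samples,
            "seed": self.seed,
        }


def _log_levene_const(n: int, allele_counts: list[int]) -> float:
    two_n = sum(allele_counts)
    assert two_n == 2 * n
    return (
        gammaln(n + 1)
        + sum(gammaln(c + 1) for c in allele_counts)
        - gammaln(two_n + 1)
    )


def log_conditional_probability(t: GenotypeCountTable) -> float:
    """log P(t | allele counts) under Levene's distribution."""
    n = t.n
    if n == 0:
        raise InputError("empty genotype table")
    allele_counts = t.allele_counts
    const = _log_levene_const(n, list(allele_counts.values()))
    h = t.heterozygote_count
    log_denom = sum(gammaln(c + 1) for c in t.counts.values())
    return const + h * _LOG2 - log_denom


def conditional_probability(t: GenotypeCountTable) -> float:
    """P(t | allele counts): Levene's conditional probability of a table."""
    return math.exp(log_conditional_probability(t))


def enumerate_genotype_tables(
    allele_copy_counts: dict[str, int],
    cap: int = DEFAULT_ENUMERATION_CAP,
    locus: str = "locus",
) -> Iterator[GenotypeCountTable]:
    """Yield every genotype table consistent with the allele copy counts.

    Tables are generated by filling the upper triangle of the genotype
    count matrix cell by cell, pruning branches whose row totals cannot be
    completed. Raises :class:`~hlapop.errors.EnumerationCapError` once more
    than ``cap`` tables have been produced.
    """
    total = sum(allele_copy_counts.values())
    if total % 2 != 0:
        raise InputError("allele copy counts must sum to an even number")
    names = sorted(allele_copy_counts)
    k = len(names)
    remaining = [allele_copy_counts[a] for a in names]
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    counts: dict[tuple[int, int], int] = {}
    yielded = 0

    def rec(idx: int) -> Iterator[GenotypeCountTable]:
        nonlocal yielded
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                yielded += 1
                if yielded > cap:
                    raise EnumerationCapError(
                        f"more than {cap} genotype tables; use Monte-Carlo"
                    )
                yield GenotypeCountTable(
                    locus=locus,
                    counts={
                        (names[i], names[j]): c
                        for (i, j), c in counts.items()
                        if c > 0
                    },
                )
            return
        i, j = cells[idx]
        last_for_i = (j == k - 1)
        if i == j:
            hi = remaining[i] // 2
            for c in range(hi + 1):
                remaining[i] -= 2 * c
                if not (last_for_i and remaining[i] != 0):
                    counts[(i, j)] = c
                    yield from rec(idx + 1)
                    del counts[(i, j)]
                remaining[i] += 2 * c
        else:
            hi = min(remaining[i], remaining[j])
            for c in range(hi + 1):
                remaining[i] -= c
                remaining[j] -= c
                if not (last_for_i and remaining[i] != 0):
                    counts[(i, j)] = c
                    yield from rec(idx + 1)
                    del counts[(i, j)]
                remaining[i] += c
                remaining[j] += c

    yield from rec(0)


def _enumeration_pvalue(
    t: GenotypeCountTable, cap: int
) -> tuple[float, int]:
    log_obs = log_conditional_probability(t)
    tail: list[float] = []
    full: list[float] = []
    n_tables = 0
    for table in enumerate_genotype_tables(
        t.allele_counts, cap=cap, locus=t.locus
    ):
        n_tables += 1
        lp = log_conditional_probability(table)
        full.append(lp)
        if lp <= log_obs + _LOG_TIE:
            tail.append(lp)
    # normalise by the enumerated total so rounding cannot push p off 1
    p = float(np.exp(logsumexp(tail) - logsumexp(full)))
    return min(p, 1.0), n_tables


def _mc_pvalue(
    t: GenotypeCountTable, mc_samples: int, seed: int
) -> float:
    """Monte-Carlo tail estimate by random pairing of the copy multiset.

    Vectorised: each sampled table comes from one row-wise permutation of
    the 2n allele copies paired off consecutively. The observed table is
    included in both numerator and denominator, keeping the estimate a
    valid p-value.
    """
    rng = np.random.default_rng(seed)
    allele_counts = t.allele_counts
    names = sorted(allele_counts)
    k = len(names)
    copies = np.repeat(
        np.arange(k, dtype=np.int64), [allele_counts[a] for a in names]
    )
    two_n = copies.size
    n = two_n // 2
    const = _log_levene_const(n, [allele_counts[a] for a in names])
    log_obs = log_conditional_probability(t)

    chunk = max(1, _MC_CHUNK_ELEMENTS // two_n)
    hits = 0
    done = 0
    while done < mc_samples:
        s = min(chunk, mc_samples - done)
        mat = rng.permuted(np.tile(copies, (s, 1)), axis=1)
        a, b = mat[:, 0::2], mat[:, 1::2]
        lo, hi_ = np.minimum(a, b), np.maximum(a, b)
        pid = lo * k + hi_
        h = (a != b).sum(axis=1)
        flat = pid + (np.arange(s)[:, None] * (k * k))
        cnt = np.bincount(flat.ravel(), minlength=s * k * k).reshape(s, k * k)
        log_p = const + h * _LOG2 - gammaln(cnt + 1).sum(axis=1)
        hits += int((log_p <= log_obs + _LOG_TIE).sum())
        done += s
    return (hits + 1) / (mc_samples + 1)


def count_genotype_tables(
    allele_copy_counts: dict[str, int], cap: int = DEFAULT_ENUMERATION_CAP
) -> int | None:
    """Number of tables consistent with the margins, or None when > cap."""
    try:
        return sum(
            1 for _ in enumerate_genotype_tables(allele_copy_counts, cap=cap)
        )
    except EnumerationCapError:
        return None


def exact_hwe_test(
    t: GenotypeCountTable,
    method: Literal["auto", "enumeration", "monte_carlo"] = "auto",
    mc_samples: int = DEFAULT_MC_SAMPLES,
    seed: int | None = None,
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP,
) -> HWEResult:
    """Exact test for deviation from Hardy-Weinberg proportions.

    ``method='auto'`` enumerates exhaustively while the table space stays
    under ``enumeration_cap`` and falls back to Monte-Carlo otherwise.
    Monte-Carlo requires a seed and at least 1,000 samples (smaller runs
    give unstable tail estimates and are refused).
    """
    if t.n == 0:
        raise InputError("empty genotype table")

    def run_mc() -> HWEResult:
        if seed is None:
            raise InputError("Monte-Carlo HWE test requires a seed")
        if mc_samples < 1_000:
            raise InputError(
                f"mc_samples must be >= 1000, got {mc_samples}"
            )
        p = _mc_pvalue(t, mc_samples, seed)
        return HWEResult(
            locus=t.locus,
            p_value=p,
            method="monte_carlo",
            observed_conditional_probability=conditional_probability(t),
            mc_samples=mc_samples,
            seed=seed,
        )

    if method == "monte_carlo":
        return run_mc()
    try:
        p, n_tables = _enumeration_pvalue(t, cap=enumeration_cap)
    except EnumerationCapError:
        if method == "enumeration":
            raise
        return run_mc()
    return HWEResult(
        locus=t.locus,
        p_value=p,
        method="enumeration",
        observed_conditional_probability=conditional_probability(t),
        tables_enumerated=n_tables,
    )
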