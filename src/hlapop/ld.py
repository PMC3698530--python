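"""Pairwise linkage disequilibrium between two multiallelic loci.

For alleles i at locus A and j at locus B with haplotype frequency p_ij
and marginals p_i, q_j, the disequilibrium coefficient is
D_ij = p_ij - p_i q_j, normalised to Lewontin's D'_ij by the largest
|D| the marginals allow. The single multiallelic summary is Hedrick's
frequency-weighted mean of |D'_ij|,

    D' = Σ_i Σ_j p_i q_j |D'_ij|,

with Cramér's-V analogue W_n available as a second summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

from .cohort import Cohort
from .haplotypes import HaplotypeFrequencySpectrum, em_haplotype_frequencies


@dataclass(frozen=True)
class PairLD:
    """LD for one allele pair: raw D, normalised D', degeneracy flag."""

    d: float
    dprime: float
    degenerate: bool = False


def dprime_pair(p_ij: float, p_i: float, q_j: float) -> PairLD:
    """Lewontin-normalised D' for one allele pair.

    A fixed or absent allele at either locus makes D undefined; such pairs
    report D' = 0 with ``degenerate=True``.
    """
    for name, v in (("p_ij", p_ij), ("p_i", p_i), ("q_j", q_j)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if p_ij > min(p_i, q_j) + 1e-12:
        raise ValueError(
            f"p_ij={p_ij} exceeds its margin min({p_i}, {q_j})"
        )
    if p_i in (0.0, 1.0) or q_j in (0.0, 1.0):
        return PairLD(d=0.0, dprime=0.0, degenerate=True)
    d = p_ij - p_i * q_j
    if d == 0.0:
        return PairLD(d=0.0, dprime=0.0)
    if d > 0:
        dmax = min(p_i * (1.0 - q_j), (1.0 - p_i) * q_j)
    else:
        dmax = min(p_i * q_j, (1.0 - p_i) * (1.0 - q_j))
    return PairLD(d=d, dprime=d / dmax)


@dataclass(frozen=True)
class LDSummary:
    """All pairwise D/D' values for one locus pair plus pooled summaries."""

    locus_a: str
    locus_b: str
    table: pd.DataFrame  # columns: allele_a, allele_b, p_ij, p_i, q_j, D, Dprime
    overall_dprime: float
    wn: float
    degenerate: bool = False


def pairwise_ld(
    source: HaplotypeFrequencySpectrum | Cohort,
    locus_a: str,
    locus_b: str,
    seed: int = 0,
) -> LDSummary:
    """LD summary between two loci from a spectrum or an unphased cohort.

    Given a cohort, two-locus haplotype frequencies are first estimated by
    EM (mirroring the estimate-then-summarise pipeline order); a spectrum
    over more loci is collapsed to the requested pair.
    """
    if isinstance(source, Cohort):
        spectrum = em_haplotype_frequencies(
            source, (locus_a, locus_b), seed=seed
        )
    else:
        spectrum = source
    if set(spectrum.loci) != {locus_a, locus_b} or len(spectrum.loci) != 2:
        spectrum = spectrum.pair_marginal(locus_a, locus_b)
    if spectrum.loci != (locus_a, locus_b):
        spectrum = spectrum.pair_marginal(locus_a, locus_b)

    p = spectrum.marginal(locus_a)
    q = spectrum.marginal(locus_b)
    joint = {
        (h[0], h[1]): f for h, f in spectrum.freqs.items()
    }

    rows = []
    overall = 0.0
    chi2_scaled = 0.0  # Σ D_ij^2 / (p_i q_j)
    any_nondegenerate = False
    for ai in sorted(p, key=lambda a: a.name):
        for bj in sorted(q, key=lambda a: a.name):
            if p[ai] <= 0.0 or q[bj] <= 0.0:
                continue
            pij = joint.get((ai, bj), 0.0)
            pair = dprime_pair(min(pij, min(p[ai], q[bj])), p[ai], q[bj])
            if not pair.degenerate:
                any_nondegenerate = True
            rows.append(
                {
                    "allele_a": ai.name, "allele_b": bj.name,
                    "p_ij": pij, "p_i": p[ai], "q_j": q[bj],
                    "D": pair.d, "Dprime": pair.dprime,
                    "degenerate": pair.degenerate,
                }
            )
            overall += p[ai] * q[bj] * abs(pair.dprime)
            chi2_scaled += pair.d ** 2 / (p[ai] * q[bj])

    k_a = sum(1 for v in p.values() if v > 0.0)
    k_b = sum(1 for v in q.values() if v > 0.0)
    degenerate = not any_nondegenerate
    if degenerate:
        overall = 0.0
        wn = 0.0
    else:
        wn = math.sqrt(chi2_scaled / min(k_a - 1, k_b - 1))
    return LDSummary(
        locus_a=locus_a,
        locus_b=locus_b,
        table=pd.DataFrame(rows),
        overall_dprime=overall,
        wn=wn,
        degenerate=degenerate,
    )
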