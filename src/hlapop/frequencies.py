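"""Direct-counting allele and carrier frequencies, and Hardy-Weinberg
expected genotype counts.

Allele frequency AF is the proportion of chromosomes (2·n_typed) carrying
an allele; carrier frequency GF is the proportion of individuals carrying
at least one copy. Both are computed on the individuals actually typed at
the locus, so per-locus missingness does not bias other loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort, FrequencyTable
from .errors import EmptyLocusError


@dataclass(frozen=True)
class HWEExpectation:
    """Expected homozygote / heterozygous-carrier counts under HWE.

    For an allele at frequency ``p`` in a cohort of ``n`` individuals under
    Hardy-Weinberg proportions, ``n p**2`` individuals are expected to be
    homozygous and ``2 n p (1 - p)`` to carry exactly one copy. Values are
    continuous; rounded views are provided for planning tables.
    """

    p: float
    n: int
    expected_homozygotes: float
    expected_heterozygote_carriers: float

    @property
    def rounded_homozygotes(self) -> int:
        return round(self.expected_homozygotes)

    @property
    def rounded_heterozygote_carriers(self) -> int:
        return round(self.expected_heterozygote_carriers)


def hwe_expected_counts(p: float, n: int) -> HWEExpectation:
    """Expected homozygotes (n·p²) and single-copy carriers (n·2p(1−p))."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"cohort size must be >= 0, got {n}")
    return HWEExpectation(
        p=p,
        n=n,
        expected_homozygotes=n * p * p,
        expected_heterozygote_carriers=n * 2.0 * p * (1.0 - p),
    )


def allele_frequencies(cohort: Cohort, locus: str) -> FrequencyTable:
    """Allele and carrier frequencies at one locus by direct counting.

    Returns a fully populated :class:`~hlapop.cohort.FrequencyTable`
    (allele copies, AF, carriers, GF, homozygote / heterozygote counts).
    """
    records = cohort.typed_records(locus)
    if not records:
        raise EmptyLocusError(f"no individual typed at locus {locus}")
    n_typed = len(records)

    copies: Counter = Counter()
    hom: Counter = Counter()
    het: Counter = Counter()
    for r in records:
        a, b = r.genotype[locus]
        copies[a.name] += 1
        copies[b.name] += 1
        if a == b:
            hom[a.name] += 1
        else:
            het[a.name] += 1
            het[b.name] += 1

    names = sorted(copies)
    table = pd.DataFrame(
        {
            "allele_count": [copies[a] for a in names],
            "AF": [copies[a] / (2.0 * n_typed) for a in names],
            "carrier_count": [hom[a] + het[a] for a in names],
            "GF": [(hom[a] + het[a]) / n_typed for a in names],
            "homozygote_count": [hom[a] for a in names],
            "heterozygote_count": [het[a] for a in names],
        },
        index=pd.Index(names, name="allele"),
    )
    return FrequencyTable(locus=locus, n_typed=n_typed, table=table)


def carrier_frequencies(cohort: Cohort, locus: str) -> FrequencyTable:
    """Alias of :func:`allele_frequencies`; one pass fills both AF and GF."""
    return allele_frequencies(cohort, locus)
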