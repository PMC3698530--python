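import hypothesis
import pytest

from hlapop.cohort import Cohort, GenotypeRecord
from hlapop.nomenclature import parse_allele

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


def make_cohort(genotypes, loci=None):
    """Build a cohort from {sample: {locus: ('A*01:01', 'A*02:01')}} dicts."""
    records = []
    all_loci = []
    for sid, geno in genotypes.items():
        parsed = {}
        for locus, (a, b) in geno.items():
            parsed[locus] = (parse_allele(a), parse_allele(b))
            if locus not in all_loci:
                all_loci.append(locus)
        records.append(GenotypeRecord(sid, "TEST", "test", parsed))
    return Cohort(tuple(records), tuple(loci or all_loci))


@pytest.fixture
def toy_cohort():
    """Four individuals at locus A: genotypes 01/01, 01/02, 02/03, 01/01.

    Allele copies: 01 x5, 02 x2, 03 x1 of 8 chromosomes.
    """
    return make_cohort(
        {
            "s1": {"A": ("A*01:01", "A*01:01")},
            "s2": {"A": ("A*01:01", "A*02:01")},
            "s3": {"A": ("A*02:01", "A*03:01")},
            "s4": {"A": ("A*01:01", "A*01:01")},
        }
    )


@pytest.fixture
def two_locus_cohort():
    """Two individuals at loci A and B with forced phase."""
    return make_cohort(
        {
            "s1": {"A": ("A*01:01", "A*01:01"), "B": ("B*07:02", "B*08:01")},
            "s2": {"A": ("A*01:01", "A*02:01"), "B": ("B*07:02", "B*07:02")},
        }
    )
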