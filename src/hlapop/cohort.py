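"""Cohort containers and delimited-text genotype / frequency-table I/O.

A cohort is a set of unrelated individuals with unordered diploid allele
pairs at one or more HLA loci plus population metadata. Genotype tables are
UTF-8 delimited text (tab by default, comma accepted) with a mandatory
header::

    sample_id  population  ethnicity  A_1  A_2  B_1  B_2  ...

Missing genotypes ("" or "NA") are tracked per locus: an individual
untyped at DRB1 still contributes to HLA-A counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import CohortLoadError
from .nomenclature import LOCI, Allele, parse_allele

_MISSING = {"", "NA", "NaN", "nan", "None"}


@dataclass(frozen=True)
class GenotypeRecord:
    """One individual: unordered diploid allele pairs keyed by locus.

    Pairs are stored in lexicographic order so that equal genotypes compare
    equal regardless of input column order. Loci absent from ``genotype``
    are untyped for this individual.
    """

    sample_id: str
    population: str
    ethnicity: str
    genotype: dict[str, tuple[Allele, Allele]]

    def __post_init__(self) -> None:
        norm = {}
        for locus, pair in self.genotype.items():
            if len(pair) != 2:
                raise CohortLoadError(
                    f"{self.sample_id}: locus {locus} needs exactly 2 alleles"
                )
            a, b = pair
            for al in (a, b):
                if al.locus != locus:
                    raise CohortLoadError(
                        f"{self.sample_id}: allele {al.name} filed under locus {locus}"
                    )
            norm[locus] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "genotype", norm)

    def typed_at(self, locus: str) -> bool:
        return locus in self.genotype

    def is_homozygous(self, locus: str) -> bool:
        a, b = self.genotype[locus]
        return a == b


@dataclass(frozen=True)
class Cohort:
    """A list of :class:`GenotypeRecord` with an ordered locus list."""

    records: tuple[GenotypeRecord, ...]
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortLoadError(f"duplicate sample_id(s): {', '.join(dup)}")
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "loci", tuple(self.loci))

    @property
    def n(self) -> int:
        return len(self.records)

    def typed_records(self, locus: str) -> list[GenotypeRecord]:
        """Individuals with a non-missing genotype at ``locus``."""
        return [r for r in self.records if r.typed_at(locus)]

    def n_typed(self, locus: str) -> int:
        return len(self.typed_records(locus))

    def map_alleles(self, mapping: dict[str, str]) -> "Cohort":
        """Rewrite allele names via a (from, to) name mapping.

        Names absent from the mapping pass through unchanged. Used for
        'g' ambiguity-group reallocation with a user-supplied table.
        """
        parsed = {src: parse_allele(dst) for src, dst in mapping.items()}

        def rewrite(a: Allele) -> Allele:
            return parsed.get(a.name, a)

        new_records = [
            GenotypeRecord(
                r.sample_id,
                r.population,
                r.ethnicity,
                {loc: (rewrite(a), rewrite(b)) for loc, (a, b) in r.genotype.items()},
            )
            for r in self.records
        ]
        return Cohort(tuple(new_records), self.loci)


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_cohort(path, sep: str | None = None) -> Cohort:
    """Load a cohort from a delimited genotype table.

    Raises :class:`~hlapop.errors.CohortLoadError` with the offending
    row/column on malformed input (odd allele columns, duplicate sample
    ids, unparseable allele names).
    """
    path = Path(path)
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = ["sample_id", "population", "ethnicity"]
    for col in required:
        if col not in df.columns:
            raise CohortLoadError(f"{path}: missing required column {col!r}")

    allele_cols = [c for c in df.columns if c not in required]
    by_locus: dict[str, list[str]] = {}
    for col in allele_cols:
        if "_" not in col:
            raise CohortLoadError(f"{path}: unrecognised column {col!r}")
        locus, _, idx = col.rpartition("_")
        if locus not in LOCI or idx not in {"1", "2"}:
            raise CohortLoadError(f"{path}: unrecognised column {col!r}")
        by_locus.setdefault(locus, []).append(col)
    loci = []
    for locus, cols in by_locus.items():
        if sorted(cols) != [f"{locus}_1", f"{locus}_2"]:
            raise CohortLoadError(
                f"{path}: locus {locus} needs exactly columns "
                f"{locus}_1 and {locus}_2, got {sorted(cols)}"
            )
        loci.append(locus)
    loci = [l for l in LOCI if l in loci]  # canonical order

    records = []
    for row_idx, row in df.iterrows():
        genotype: dict[str, tuple[Allele, Allele]] = {}
        for locus in loci:
            raw1 = row[f"{locus}_1"].strip()
            raw2 = row[f"{locus}_2"].strip()
            miss1, miss2 = raw1 in _MISSING, raw2 in _MISSING
            if miss1 != miss2:
                raise CohortLoadError(
                    f"{path}: row {row_idx + 2}: locus {locus} half-missing"
                )
            if miss1:
                continue
            try:
                genotype[locus] = (parse_allele(raw1), parse_allele(raw2))
            except Exception as exc:
                raise CohortLoadError(
                    f"{path}: row {row_idx + 2}, locus {locus}: {exc}"
                ) from exc
        records.append(
            GenotypeRecord(
                row["sample_id"], row["population"], row["ethnicity"], genotype
            )
        )
    try:
        return Cohort(tuple(records), tuple(loci))
    except CohortLoadError as exc:
        raise CohortLoadError(f"{path}: {exc}") from exc


def write_cohort(cohort: Cohort, path, sep: str = "\t") -> None:
    """Write a cohort back to delimited text (inverse of :func:`read_cohort`)."""
    cols = ["sample_id", "population", "ethnicity"]
    for locus in cohort.loci:
        cols += [f"{locus}_1", f"{locus}_2"]
    rows = []
    for r in cohort.records:
        row = {"sample_id": r.sample_id, "population": r.population,
               "ethnicity": r.ethnicity}
        for locus in cohort.loci:
            if r.typed_at(locus):
                a, b = r.genotype[locus]
                row[f"{locus}_1"], row[f"{locus}_2"] = a.name, b.name
            else:
                row[f"{locus}_1"] = row[f"{locus}_2"] = "NA"
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


@dataclass
class FrequencyTable:
    """Per-allele counts and frequencies at one locus.

    ``AF`` is the allele frequency (copies / 2·n_typed chromosomes); ``GF``
    is the carrier frequency (individuals carrying ≥1 copy / n_typed).
    The underlying frame is full precision; display rounding (3 decimals
    AF, 1 decimal GF%) happens only at serialization.
    """

    locus: str
    n_typed: int
    table: pd.DataFrame = field(repr=False)

    _COLS = ("allele_count", "AF", "carrier_count", "GF",
             "homozygote_count", "heterozygote_count")

    def __post_init__(self) -> None:
        if self.n_typed > 0 and not math.isclose(
            float(self.table["AF"].sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError(
                f"{self.locus}: allele frequencies sum to "
                f"{self.table['AF'].sum():.12f}, not 1"
            )

    @property
    def alleles(self) -> list[str]:
        return list(self.table.index)

    def af(self, allele_name: str) -> float:
        return float(self.table.at[allele_name, "AF"])

    def gf(self, allele_name: str) -> float:
        if allele_name not in self.table.index:
            return 0.0
        return float(self.table.at[allele_name, "GF"])

    def top_alleles(self, m: int, exclude: set[str] | None = None) -> list[str]:
        """The ``m`` most frequent allele names, optionally excluding a set.

        Frequency ties break lexicographically for determinism.
        """
        exclude = exclude or set()
        ranked = sorted(
            (a for a in self.table.index if a not in exclude),
            key=lambda a: (-self.table.at[a, "AF"], a),
        )
        return ranked[:m]


def write_frequency_table(t: FrequencyTable, path) -> None:
    """Serialize a frequency table as TSV with conventional display rounding.

    AF is printed to three decimal places and carrier frequency as a
    percentage to one decimal; a trailing ``TOTAL`` row carries the AF
    column sum. Counts round-trip exactly.
    """
    df = t.table
    out = pd.DataFrame(
        {
            "allele": df.index,
            "allele_count": df["allele_count"].astype(int).to_numpy(),
            "AF": [f"{v:.3f}" for v in df["AF"]],
            "carrier_count": df["carrier_count"].astype(int).to_numpy(),
            "GF_percent": [f"{100 * v:.1f}" for v in df["GF"]],
            "hom": df["homozygote_count"].astype(int).to_numpy(),
            "het": df["heterozygote_count"].astype(int).to_numpy(),
        }
    )
    total = {
        "allele": "TOTAL", "allele_count": int(df["allele_count"].sum()),
        "AF": f"{df['AF'].sum():.3f}",
        "carrier_count": "", "GF_percent": "", "hom": "", "het": "",
    }
    out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# locus={t.locus}\tn_typed={t.n_typed}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_frequency_table(path) -> FrequencyTable:
    """Read back a TSV written by :func:`write_frequency_table`.

    Frequencies are recomputed from the integer counts (the printed AF/GF
    columns are display-rounded).
    """
    with open(path, encoding="utf-8") as fh:
        meta = fh.readline().lstrip("#").strip()
        df = pd.read_csv(fh, sep="\t", dtype=str)
    fields = dict(kv.split("=") for kv in meta.split("\t"))
    locus, n_typed = fields["locus"], int(fields["n_typed"])
    df = df[df["allele"] != "TOTAL"].set_index("allele")
    counts = df[["allele_count", "carrier_count", "hom", "het"]].astype(int)
    table = pd.DataFrame(
        {
            "allele_count": counts["allele_count"],
            "AF": counts["allele_count"] / (2 * n_typed),
            "carrier_count": counts["carrier_count"],
            "GF": counts["carrier_count"] / n_typed,
            "homozygote_count": counts["hom"],
            "heterozygote_count": counts["het"],
        }
    )
    return FrequencyTable(locus=locus, n_typed=n_typed, table=table)
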