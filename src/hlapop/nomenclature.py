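"""HLA allele nomenclature: parsing, rendering and resolution truncation.

Allele names follow current WHO nomenclature, e.g. ``B*57:01:01`` —
a locus label, ``*``, then one to four colon-separated numeric fields
(allele group, protein, synonymous, non-coding). A trailing ``g`` marks an
ambiguity group: a set of alleles a sequencing strategy could not
distinguish, analysed as a single unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import AlleleParseError

#: Loci supported by the package, in canonical report order.
LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1", "DQA1")

_NAME_RE = re.compile(r"^(?P<locus>[A-Z0-9]+)\*(?P<fields>[\d:]+)(?P<g>g?)$")


@dataclass(frozen=True, order=True)
class Allele:
    """A single HLA allele (or 'g' ambiguity group) at one locus.

    Ordering is lexicographic on ``(locus, fields, g_suffix)`` which gives a
    deterministic sort for reports and genotype normalisation.
    """

    locus: str
    fields: tuple[str, ...]
    g_suffix: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown locus {self.locus!r}")
        if not self.fields:
            raise AlleleParseError("allele must have at least one field")
        for f in self.fields:
            if not (f.isdigit() and f):
                raise AlleleParseError(f"non-numeric allele field {f!r}")

    @property
    def name(self) -> str:
        """Canonical string form, e.g. ``DQB1*06:04g``."""
        return f"{self.locus}*{':'.join(self.fields)}{'g' if self.g_suffix else ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name

    def truncate(self, n_fields: int) -> "Allele":
        """Reduce resolution to the first ``n_fields`` fields.

        The 'g' suffix marks a group defined at full resolution, so any
        truncation at or below that resolution drops it and yields the
        plain allele name (the usual allocation, e.g. DQB1*06:04g ->
        DQB1*06:04); requesting more fields than exist returns the allele
        unchanged.
        """
        if n_fields < 1:
            raise ValueError(f"n_fields must be >= 1, got {n_fields}")
        if n_fields > len(self.fields):
            return self
        return Allele(self.locus, self.fields[:n_fields], g_suffix=False)


def parse_allele(name: str) -> Allele:
    """Parse an HLA allele name such as ``B*57:01:01`` or ``DQB1*06:04g``.

    Raises :class:`~hlapop.errors.AlleleParseError` naming the offending
    token on malformed input.
    """
    if not name:
        raise AlleleParseError("empty allele name")
    m = _NAME_RE.match(name.strip())
    if m is None:
        if "*" not in name:
            raise AlleleParseError(f"no '*' separator in allele name {name!r}")
        raise AlleleParseError(f"malformed allele name {name!r}")
    locus = m.group("locus")
    if locus not in LOCI:
        raise AlleleParseError(f"unknown locus {locus!r} in {name!r}")
    fields = tuple(m.group("fields").split(":"))
    if len(fields) > 4:
        raise AlleleParseError(f"more than 4 fields in {name!r}")
    for f in fields:
        if not f.isdigit():
            raise AlleleParseError(f"non-numeric field {f!r} in {name!r}")
    return Allele(locus, fields, g_suffix=(m.group("g") == "g"))


def truncate_allele(allele: Allele, n_fields: int) -> Allele:
    """Functional form of :meth:`Allele.truncate`."""
    return allele.truncate(n_fields)


def read_g_group_mapping(path) -> dict[str, str]:
    """Read a two-column (from, to) allele-name mapping file.

    Used to rewrite 'g' ambiguity codes onto plain names (e.g.
    ``A*33:03g -> A*33:03``) when the user supplies the grouping table.
    Lines starting with ``#`` and blank lines are ignored; columns are
    whitespace- or tab-separated.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise AlleleParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            src, dst = parts
            parse_allele(src), parse_allele(dst)  # validate both names
            mapping[src] = dst
    return mapping
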