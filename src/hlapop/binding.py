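"""Peptide sampling, binding-score profiles and correlation distances.

The clustering stage compares HLA alleles by the peptides they are
predicted to bind: each allele gets a profile of affinity scores in
[0, 1] over a common random peptide set, pairwise similarity is the
Pearson correlation of profiles, and distance is 1 - r. Affinity
conventions follow the usual predictor scale: scores around 0.4 suggest a
weak binder and around 0.6 a strong binder.

The scorer is pluggable: any callable mapping (allele_name, peptide) to a
score in [0, 1] works, e.g. the motif-based surrogate in
:mod:`hlapop.simulate` or a wrapper around an external predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import InputError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)

CLASS_I_PEPTIDE_LENGTH = 9   # canonical class I binding core
CLASS_II_PEPTIDE_LENGTH = 15  # conventional optimum for class II

STRONG_BINDER_CUTOFF = 0.6
WEAK_BINDER_CUTOFF = 0.4


@dataclass(frozen=True)
class PeptideSet:
    """Random peptides of a fixed length drawn from a proteome."""

    peptides: tuple[str, ...]
    k: int
    source: str
    seed: int | None

    def __post_init__(self) -> None:
        for p in self.peptides:
            if len(p) != self.k:
                raise InputError(f"peptide {p!r} is not length {self.k}")
            if not set(p) <= _AA_SET:
                raise InputError(f"non-standard residue in {p!r}")


def sample_peptides(
    proteome, k: int, n: int, seed: int, source: str | None = None
) -> PeptideSet:
    """Draw ``n`` length-``k`` substrings uniformly over all (protein,
    start) windows, with replacement.

    ``proteome`` is a FASTA path or a sequence of protein strings.
    Windows containing non-standard residues are rejected and redrawn so
    the output alphabet is the 20 standard amino acids.
    """
    if isinstance(proteome, (str, Path)):
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(proteome), "fasta")]
        src = source or str(proteome)
    else:
        seqs = [str(s).upper() for s in proteome]
        src = source or "in-memory proteome"
    windows_per_seq = np.array([max(0, len(s) - k + 1) for s in seqs])
    total = int(windows_per_seq.sum())
    if total == 0:
        raise InputError(f"no protein of length >= {k} in {src}")
    offsets = np.concatenate([[0], np.cumsum(windows_per_seq)])

    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    guard = 0
    while len(peptides) < n:
        draw = rng.integers(0, total, size=n - len(peptides))
        for flat in draw:
            si = int(np.searchsorted(offsets, flat, side="right")) - 1
            start = int(flat - offsets[si])
            pep = seqs[si][start : start + k]
            if set(pep) <= _AA_SET:
                peptides.append(pep)
        guard += 1
        if guard > 1000:
            raise InputError(
                f"could not draw {n} standard-alphabet peptides from {src}"
            )
    return PeptideSet(peptides=tuple(peptides), k=k, source=src, seed=seed)


@dataclass(frozen=True)
class BindingProfile:
    """Alleles × peptides matrix of affinity scores in [0, 1]."""

    alleles: tuple[str, ...]
    peptides: tuple[str, ...]
    scores: np.ndarray  # shape (len(alleles), len(peptides))

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.alleles), len(self.peptides)):
            raise InputError(
                f"score matrix shape {s.shape} does not match "
                f"{len(self.alleles)} alleles x {len(self.peptides)} peptides"
            )
        if np.isnan(s).any():
            raise InputError("missing cells in binding profile")
        if (s < 0).any() or (s > 1).any():
            raise InputError("binding scores must lie in [0, 1]")
        object.__setattr__(self, "scores", s)


Scorer = Callable[[str, str], float]


def score_profiles(
    alleles: Sequence[str], peptides: PeptideSet | Sequence[str], scorer: Scorer
) -> BindingProfile:
    """Score every (allele, peptide) combination into a complete profile.

    A scorer returning a value outside [0, 1] raises immediately, naming
    the offending allele and peptide.
    """
    peps = tuple(peptides.peptides if isinstance(peptides, PeptideSet) else peptides)
    mat = np.empty((len(alleles), len(peps)))
    for i, allele in enumerate(alleles):
        if hasattr(scorer, "score_many"):
            row = np.asarray(scorer.score_many(allele, peps), dtype=float)
            bad = np.flatnonzero((row < 0) | (row > 1))
            if bad.size:
                j = int(bad[0])
                raise InputError(
                    f"scorer returned {row[j]} outside [0, 1] for "
                    f"allele {allele}, peptide {peps[j]}"
                )
            mat[i] = row
        else:
            for j, pep in enumerate(peps):
                s = float(scorer(allele, pep))
                if not 0.0 <= s <= 1.0:
                    raise InputError(
                        f"scorer returned {s} outside [0, 1] for "
                        f"allele {allele}, peptide {pep}"
                    )
                mat[i, j] = s
    return BindingProfile(alleles=tuple(alleles), peptides=peps, scores=mat)


def classify_binder(score: float) -> str:
    """Classify an affinity score: >=0.6 strong, >=0.4 weak, else non-binder."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"affinity score must be in [0, 1], got {score}")
    if score >= STRONG_BINDER_CUTOFF:
        return "strong_binder"
    if score >= WEAK_BINDER_CUTOFF:
        return "weak_binder"
    return "non_binder"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal, labels attached."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise InputError("distances must be non-negative")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def correlation_distance_matrix(profile: BindingProfile) -> DistanceMatrix:
    """1 - Pearson correlation between allele score profiles.

    A zero-variance profile has no defined correlation; its correlation is
    taken as 0 (distance 1 to everything) and a warning is emitted.
    """
    if len(profile.alleles) < 2:
        raise InputError("need at least 2 alleles for a distance matrix")
    if len(profile.peptides) < 2:
        raise InputError("need at least 2 peptides per profile")
    x = profile.scores
    sd = x.std(axis=1)
    degenerate = sd == 0.0
    if degenerate.any():
        names = [a for a, d in zip(profile.alleles, degenerate) if d]
        warnings.warn(
            f"zero-variance binding profile(s): {', '.join(names)}; "
            "their correlations are taken as 0",
            stacklevel=2,
        )
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.where(degenerate, 1.0, sd * np.sqrt(x.shape[1]))
    z = xc / norm[:, None]
    r = z @ z.T
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    # identical profiles must be at distance exactly 0, not rounding dust
    d[d < 1e-12] = 0.0
    return DistanceMatrix(labels=profile.alleles, values=d)


def select_control_alleles(
    freq_table, m: int, exclude: Sequence[str] = ()
) -> list[str]:
    """Top-``m`` most frequent alleles at a locus, excluding a test set.

    The usual control design: compare alleles of interest against the most
    common genetic background that does not itself carry them.
    """
    return freq_table.top_alleles(m, exclude=set(exclude))
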