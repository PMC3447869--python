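"""Microsatellite diversity statistics for diploid genotype samples.

Implements the small set of descriptive statistics used to characterise
genetic variability in the Finnish and Oklahoma white-tailed deer samples:
Nei's unbiased gene diversity (expected heterozygosity), allelic richness
as the distinct-allele count, observed heterozygosity, over-loci summaries,
and the tie-corrected one-tailed Mann-Whitney U comparison between the
per-locus statistics of two populations.

Genotypes are held in :class:`GenotypeTable`: an ``(n_individuals, n_loci, 2)``
integer array of allele labels, where ``0`` is the reserved missing-data
sentinel and real alleles are positive integers.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

MISSING = 0  # reserved sentinel allele label for missing data

__all__ = [
    "MISSING",
    "GenotypeTable",
    "LocusSummary",
    "DiversitySummary",
    "expected_heterozygosity",
    "allelic_richness",
    "observed_heterozygosity",
    "summarize_population",
    "summarize_table",
    "mann_whitney_one_tailed",
    "subsample_complete_cases",
]


@dataclass
class GenotypeTable:
    """Multi-locus diploid genotypes for one population sample.

    Parameters
    ----------
    loci
        Ordered locus names.
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``. Allele labels
        are positive integers; ``MISSING`` (0) marks a missing allele.
    population
        Free-text population label.
    """

    loci: list[str]
    alleles: np.ndarray
    population: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_individuals, n_loci, 2)")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError(
                f"{len(self.loci)} loci but alleles array has "
                f"{self.alleles.shape[1]} locus columns"
            )
        if len(self.loci) < 1:
            raise ValueError("need at least one locus")
        if (self.alleles < 0).any():
            raise ValueError("allele labels must be non-negative integers")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def complete_case_mask(self) -> np.ndarray:
        """Boolean mask of individuals with no missing allele at any locus."""
        return (self.alleles != MISSING).all(axis=(1, 2))

    def allele_counts(self, locus: str) -> Counter:
        """Counts of non-missing gene copies by allele label at one locus."""
        col = self.alleles[:, self.locus_index(locus), :].ravel()
        return Counter(int(a) for a in col if a != MISSING)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide layout: two columns per locus, ``<locus>_1`` / ``<locus>_2``."""
        cols = {}
        for j, locus in enumerate(self.loci):
            cols[f"{locus}_1"] = self.alleles[:, j, 0]
            cols[f"{locus}_2"] = self.alleles[:, j, 1]
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, population: str = "") -> "GenotypeTable":
        """Build from the wide layout produced by :meth:`to_dataframe`."""
        loci: list[str] = []
        for col in df.columns:
            if col.endswith("_1"):
                locus = col[:-2]
                if f"{locus}_2" not in df.columns:
                    raise ValueError(f"column {col} has no matching {locus}_2")
                loci.append(locus)
        if not loci:
            raise ValueError("no '<locus>_1'/'<locus>_2' column pairs found")
        arr = np.stack(
            [np.column_stack([df[f"{l}_1"], df[f"{l}_2"]]) for l in loci], axis=1
        )
        return cls(loci=loci, alleles=arr, population=population)


@dataclass(frozen=True)
class LocusSummary:
    """Allelic richness and expected heterozygosity at one locus."""

    locus: str
    allele_count: int
    expected_het: float

    def __post_init__(self) -> None:
        if self.allele_count < 1:
            raise ValueError("allele_count must be >= 1")
        if not 0.0 <= self.expected_het <= 1.0:
            raise ValueError("expected_het must lie in [0, 1]")
        if self.allele_count == 1 and self.expected_het != 0.0:
            raise ValueError("a monomorphic locus has expected_het 0")


@dataclass(frozen=True)
class DiversitySummary:
    """Over-loci mean diversity plus the per-locus breakdown."""

    mean_expected_het: float
    mean_allelic_richness: float
    per_locus: tuple[LocusSummary, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s.locus, s.allele_count, s.expected_het) for s in self.per_locus]
        rows.append(("Over loci", self.mean_allelic_richness, self.mean_expected_het))
        return pd.DataFrame(rows, columns=["locus", "allelic_richness", "expected_het"])


def _counts(allele_counts: Mapping) -> tuple[np.ndarray, int]:
    counts = np.array([c for c in allele_counts.values() if c > 0], dtype=float)
    return counts, int(counts.sum())


def expected_heterozygosity(allele_counts: Mapping) -> float:
    """Nei's unbiased gene diversity from gene-copy counts at one locus.

    With ``n`` sampled gene copies carrying alleles at sample frequencies
    ``p_i``, returns ``(n / (n - 1)) * (1 - sum(p_i**2))``, clipped to
    ``[0, 1]``. Requires ``n >= 2``.
    """
    counts, n = _counts(allele_counts)
    if n < 2:
        raise ValueError("expected heterozygosity is undefined for fewer than 2 gene copies")
    p = counts / n
    h = n / (n - 1.0) * (1.0 - float(np.sum(p * p)))
    return float(np.clip(h, 0.0, 1.0))


def allelic_richness(allele_counts: Mapping) -> int:
    """Number of distinct alleles observed at one locus.

    Both samples compared here hold exactly 72 complete-case individuals,
    so rarefaction to the smaller sample is the identity and the raw count
    is the allelic richness.
    """
    counts, n = _counts(allele_counts)
    if n < 1:
        raise ValueError("no observed alleles at locus")
    return int(len(counts))


def observed_heterozygosity(table: GenotypeTable, locus: str) -> float:
    """Fraction of non-missing individuals heterozygous at ``locus``."""
    pair = table.alleles[:, table.locus_index(locus), :]
    ok = (pair != MISSING).all(axis=1)
    if not ok.any():
        raise ValueError(f"all genotypes missing at locus {locus!r}")
    return float(np.mean(pair[ok, 0] != pair[ok, 1]))


def summarize_population(per_locus: Sequence[LocusSummary]) -> DiversitySummary:
    """Arithmetic over-loci means of allele count and expected heterozygosity."""
    if len(per_locus) == 0:
        raise ValueError("need at least one locus summary")
    return DiversitySummary(
        mean_expected_het=float(np.mean([s.expected_het for s in per_locus])),
        mean_allelic_richness=float(np.mean([s.allele_count for s in per_locus])),
        per_locus=tuple(per_locus),
    )


def summarize_table(table: GenotypeTable) -> DiversitySummary:
    """Per-locus and over-loci diversity of a genotype table.

    Individuals with missing data at a locus are dropped for that locus only.
    """
    per_locus = []
    for locus in table.loci:
        counts = table.allele_counts(locus)
        per_locus.append(
            LocusSummary(
                locus=locus,
                allele_count=allelic_richness(counts),
                expected_het=expected_heterozygosity(counts),
            )
        )
    return summarize_population(per_locus)


def mann_whitney_one_tailed(
    sample_x: Sequence[float], sample_y: Sequence[float]
) -> tuple[float, float]:
    """Tie-corrected normal-approximation Mann-Whitney U test.

    Returns ``(Z, p_one_tailed)`` with no continuity correction, the
    convention of mainstream commercial statistics packages. ``Z`` is signed
    so that a smaller mean rank of ``sample_x`` gives a negative value, and
    the one-tailed p is ``Phi(Z)`` — i.e. the p-value for the directional
    alternative that ``sample_x`` is stochastically smaller than ``sample_y``.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = _sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0.0:  # all observations identical
        return 0.0, 0.5
    z = (u1 - mu) / np.sqrt(var)
    return float(z), float(_sps.norm.cdf(z))


def subsample_complete_cases(
    table: GenotypeTable, n: int, seed: int | np.random.Generator
) -> GenotypeTable:
    """Draw ``n`` fully genotyped individuals uniformly without replacement.

    Mirrors the sampling convention used to match the 72-individual
    comparison sample: only individuals with no missing data at any locus
    are eligible. Reproducible for a fixed ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = np.flatnonzero(table.complete_case_mask())
    if len(idx) < n:
        raise ValueError(f"only {len(idx)} complete cases available, need {n}")
    chosen = np.sort(rng.choice(idx, size=n, replace=False))
    return GenotypeTable(
        loci=list(table.loci),
        alleles=table.alleles[chosen],
        population=table.population,
    )
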