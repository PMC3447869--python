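"""Founder genotype construction for the introduction scenarios.

The composition of the four founders (3 females, 1 male) is unknown beyond
plausible constraints, so the simulator explores bracketing schemes:

``max_het``
    every founder heterozygous at every locus while the locus displays a
    prescribed number of distinct alleles (scenario A1, and scenario C's
    resident population);
``min_het``
    the minimal attainable number of heterozygous founders given the same
    allele counts (scenario A2);
``max_ar``
    all ``2n`` founder gene copies distinct — 8 alleles per locus for four
    founders, which forces full heterozygosity (scenario B).

Allele labels are opaque positive integers (1..k per locus); microsatellite
repeat sizes and mutation are not modelled.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datasets import LOCI, finland_allelic_richness

__all__ = [
    "FounderSpec",
    "IntroductionEvent",
    "min_founder_heterozygosity",
    "build_founders",
    "build_introduction_cohort",
]

SCHEMES = ("max_het", "min_het", "max_ar")


@dataclass(frozen=True)
class FounderSpec:
    """Founder cohort composition and genotype construction scheme."""

    n_females: int = 3
    n_males: int = 1
    loci: tuple[str, ...] = tuple(LOCI)
    ar_per_locus: tuple[int, ...] = ()
    scheme: str = "max_het"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.n_females < 0 or self.n_males < 0 or self.n_founders < 1:
            raise ValueError("need a non-negative sex split with at least one founder")
        ar = self.ar_per_locus or tuple(finland_allelic_richness())
        object.__setattr__(self, "ar_per_locus", tuple(int(k) for k in ar))
        if len(self.ar_per_locus) != len(self.loci):
            raise ValueError("ar_per_locus must give one allele count per locus")
        cap = 2 * self.n_founders
        for locus, k in zip(self.loci, self.ar_per_locus):
            if not 1 <= k <= cap:
                raise ValueError(
                    f"locus {locus}: {k} alleles impossible among {cap} gene copies"
                )
            if self.scheme == "max_ar" and k != cap:
                raise ValueError("max_ar scheme requires ar_per_locus == 2 * n_founders")

    @property
    def n_founders(self) -> int:
        return self.n_females + self.n_males


@dataclass(frozen=True)
class IntroductionEvent:
    """A later release of novel-genotype individuals (scenario C).

    Defaults match the 1949 restocking attempt: one male and three females
    released as yearlings fifteen time steps after founding, each fully
    heterozygous with alleles novel to the resident population.
    """

    time_step: int = 15
    n_females: int = 3
    n_males: int = 1
    age_at_release: int = 1
    genotype_scheme: str = "novel_fully_heterozygous"

    def __post_init__(self) -> None:
        if self.time_step < 0:
            raise ValueError("time_step must be >= 0")
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("cohort counts must be >= 0")


def min_founder_heterozygosity(ar_per_locus: Sequence[int], n_founders: int) -> float:
    """Minimal mean individual heterozygosity displaying given allele counts.

    With ``n`` diploid founders that must jointly display ``k_i`` distinct
    alleles at locus ``i``, at least ``max(0, k_i - n)`` founders are forced
    to be heterozygous there (each homozygote displays one allele, each
    heterozygote at most two). The minimum of the founder-mean, locus-mean
    heterozygosity is therefore ``sum_i max(0, k_i - n) / (n * L)``.

    For the Finnish allele counts and four founders this evaluates to
    22/56 ≈ 0.39, the scenario-A2 starting heterozygosity.
    """
    if n_founders < 1:
        raise ValueError("need at least one founder")
    ks = [int(k) for k in ar_per_locus]
    if not ks:
        raise ValueError("need at least one locus")
    for k in ks:
        if not 1 <= k <= 2 * n_founders:
            raise ValueError(f"{k} alleles impossible among {2 * n_founders} gene copies")
    forced = sum(max(0, k - n_founders) for k in ks)
    return forced / (n_founders * len(ks))


def _locus_genotypes(k: int, n: int, scheme: str) -> np.ndarray:
    """Allele pairs (n, 2) for one locus with exactly k distinct labels 1..k."""
    if scheme == "max_ar":
        labels = np.arange(1, 2 * n + 1)
        return labels.reshape(n, 2)
    if scheme == "max_het":
        if k < 2:
            raise ValueError(
                "max_het infeasible for a monomorphic locus: a single allele "
                "cannot form a heterozygote"
            )
        # round-robin the k labels over the 2n gene copies (as even a
        # frequency spectrum as the count constraint allows), then pair
        # consecutive copies: consecutive round-robin labels differ for k >= 2.
        copies = np.resize(np.arange(1, k + 1), 2 * n)
        return copies.reshape(n, 2)
    if scheme == "min_het":
        n_het = max(0, k - n)
        pairs = []
        for i in range(n_het):  # forced heterozygotes carry two unique alleles
            pairs.append((2 * i + 1, 2 * i + 2))
        remaining = list(range(2 * n_het + 1, k + 1)) or [1]
        for i in range(n - n_het):  # the rest are homozygous, recycling labels
            a = remaining[i % len(remaining)]
            pairs.append((a, a))
        return np.array(pairs, dtype=np.int64)
    raise ValueError(f"unknown scheme {scheme!r}")


def build_founders(spec: FounderSpec, seed: int | None = None) -> np.ndarray:
    """Construct founder genotypes: array ``(n_founders, n_loci, 2)``.

    Per locus, exactly ``ar_per_locus`` distinct allele labels appear among
    the founders, arranged per the requested scheme. The construction is
    deterministic; ``seed`` is accepted for interface symmetry only.
    """
    n = spec.n_founders
    per_locus = [
        _locus_genotypes(k, n, spec.scheme) for k in spec.ar_per_locus
    ]
    return np.stack(per_locus, axis=1)


def build_introduction_cohort(
    event: IntroductionEvent, existing_allele_labels: Iterable[Iterable[int]]
) -> np.ndarray:
    """Genotypes for a novel-allele release cohort: ``(n, n_loci, 2)``.

    Every individual is heterozygous at every locus, and every allele label
    is distinct both from all ``existing_allele_labels`` at that locus and
    from every other cohort allele — 8 novel alleles per locus for a
    four-animal cohort.
    """
    n = event.n_females + event.n_males
    existing = [set(int(a) for a in labels) for labels in existing_allele_labels]
    if n == 0:
        return np.empty((0, len(existing), 2), dtype=np.int64)
    per_locus = []
    for labels in existing:
        base = max(labels) if labels else 0
        novel = np.arange(base + 1, base + 2 * n + 1)
        per_locus.append(novel.reshape(n, 2))
    return np.stack(per_locus, axis=1)
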