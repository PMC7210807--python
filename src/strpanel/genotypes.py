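"""Core domain types for STR panels: loci, alleles, genotypes and populations.

Alleles follow the ISFG repeat-based nomenclature: an allele is named by the
number of complete repeats of the locus motif, with a microvariant suffix for
alleles whose length is not an integer multiple of the motif (e.g. ``13.2`` is
13 full repeats plus 2 extra bases).  Genotypes are unordered pairs of alleles
at one locus; populations are cohorts of diploid individuals with possibly
partial genotype tables (hair-sample panels routinely drop loci).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional


class StrPanelError(Exception):
    """Base class for all package errors."""


class NoTypedIndividualsError(StrPanelError):
    """Raised when an estimate is requested at a locus no individual is typed at."""


class LocusMismatchError(StrPanelError):
    """Raised when genotypes from different loci are combined."""


_ALLELE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


@dataclass(frozen=True, order=True)
class AlleleName:
    """Repeat-based allele designation, ordered by (repeats, microvariant).

    ``microvariant`` counts the extra bases beyond complete motif repeats and
    must be smaller than the motif length of the owning locus (at most 4, for
    pentanucleotide motifs).
    """

    repeats: int
    microvariant: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0:
            raise ValueError(f"negative repeat count: {self.repeats}")
        if not 0 <= self.microvariant <= 4:
            raise ValueError(f"microvariant out of range: {self.microvariant}")

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        """Parse ``"14"``, ``"13.2"`` (and ``"14.0"``, rendered back as ``"14"``)."""
        m = _ALLELE_RE.match(str(text).strip())
        if m is None:
            raise ValueError(f"cannot parse allele name {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))

    def __str__(self) -> str:
        if self.microvariant == 0:
            return str(self.repeats)
        return f"{self.repeats}.{self.microvariant}"


@dataclass(frozen=True)
class Locus:
    """A named STR marker.

    ``motif`` is the repeat unit (tetra- or pentanucleotide for panel-grade
    markers); it may be ``None`` for loci known only from a frequency table.
    """

    name: str
    motif: Optional[str] = None
    chromosome_label: Optional[str] = None
    size_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.motif is not None:
            if not re.fullmatch(r"[ACGT]+", self.motif):
                raise ValueError(f"{self.name}: motif must be uppercase A/C/G/T, got {self.motif!r}")
            if len(self.motif) not in (4, 5):
                raise ValueError(
                    f"{self.name}: panel loci are tetra- or pentanucleotide repeats, "
                    f"got motif length {len(self.motif)}"
                )
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError(f"{self.name}: inverted size range {self.size_range}")

    @property
    def motif_length(self) -> Optional[int]:
        return None if self.motif is None else len(self.motif)

    def validate_allele(self, allele: AlleleName) -> None:
        if self.motif is not None and allele.microvariant >= len(self.motif):
            raise ValueError(
                f"{self.name}: microvariant .{allele.microvariant} is not smaller "
                f"than the motif length {len(self.motif)}"
            )


@dataclass(frozen=True)
class Genotype:
    """Unordered pair of alleles at one locus; stored sorted so that
    ``Genotype(l, a, b) == Genotype(l, b, a)``."""

    locus: str
    a1: AlleleName
    a2: AlleleName

    def __init__(self, locus: str, a1: AlleleName, a2: AlleleName) -> None:
        lo, hi = sorted((a1, a2))
        object.__setattr__(self, "locus", locus)
        object.__setattr__(self, "a1", lo)
        object.__setattr__(self, "a2", hi)

    @property
    def alleles(self) -> tuple[AlleleName, AlleleName]:
        return (self.a1, self.a2)

    @property
    def is_homozygous(self) -> bool:
        return self.a1 == self.a2

    def __str__(self) -> str:
        return f"{self.a1}/{self.a2}"


@dataclass
class Individual:
    """A sampled animal: id, per-locus genotypes (possibly partial), optional sex."""

    id: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    sex_call: Optional[str] = None  # "XX", "XY" or None/unknown

    def set_genotype(self, genotype: Genotype) -> None:
        self.genotypes[genotype.locus] = genotype


@dataclass
class Population:
    """A cohort of individuals; ``n`` is the cohort size, 2n chromosomes per
    fully typed locus."""

    individuals: list[Individual] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def typed_at(self, locus_name: str) -> list[Individual]:
        return [ind for ind in self.individuals if locus_name in ind.genotypes]

    def allele_counts(self, locus_name: str) -> Counter:
        counts: Counter = Counter()
        for ind in self.typed_at(locus_name):
            g = ind.genotypes[locus_name]
            counts[g.a1] += 1
            counts[g.a2] += 1
        return counts

    def genotype_counts(self, locus_name: str) -> Counter:
        return Counter(ind.genotypes[locus_name] for ind in self.typed_at(locus_name))

    def locus_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            for name in ind.genotypes:
                seen.setdefault(name)
        return list(seen)


# Published tables are rounded to 4 decimals, so a per-locus frequency column
# may miss 1 by a few 1e-4; internally estimated tables must sum to 1 exactly.
PUBLISHED_SUM_TOL = 5e-4


@dataclass
class FrequencyTable:
    """Per-locus allele relative frequencies, optionally backed by exact counts."""

    locus: Locus
    freqs: dict[AlleleName, float]
    counts: Optional[dict[AlleleName, int]] = None
    n_chromosomes: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.freqs:
            raise ValueError(f"{self.locus.name}: empty frequency table")
        for a, p in self.freqs.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"{self.locus.name}: frequency of allele {a} out of (0,1]: {p}")
            self.locus.validate_allele(a)
        total = sum(self.freqs.values())
        if abs(total - 1.0) > PUBLISHED_SUM_TOL:
            raise ValueError(f"{self.locus.name}: frequencies sum to {total}, not 1")

    @classmethod
    def from_counts(
        cls, locus: Locus, counts: Mapping[AlleleName, int]
    ) -> "FrequencyTable":
        """Exact-count constructor: frequencies are count / total, pre-rounding."""
        total = sum(counts.values())
        if total == 0:
            raise NoTypedIndividualsError(f"{locus.name}: no alleles observed")
        freqs = {a: c / total for a, c in sorted(counts.items()) if c > 0}
        return cls(locus, freqs, counts=dict(counts), n_chromosomes=total)

    @property
    def alleles(self) -> list[AlleleName]:
        return sorted(self.freqs)

    @property
    def n_alleles(self) -> int:
        return sum(1 for p in self.freqs.values() if p > 0)

    def probabilities(self) -> list[float]:
        return [self.freqs[a] for a in self.alleles]


@dataclass
class GenotypeFrequencyTable:
    """Per-locus genotype relative frequencies (the g_i of discrimination power)."""

    locus: Locus
    gfreqs: dict[Genotype, float]

    def __post_init__(self) -> None:
        if not self.gfreqs:
            raise ValueError(f"{self.locus.name}: empty genotype frequency table")
        total = sum(self.gfreqs.values())
        if abs(total - 1.0) > PUBLISHED_SUM_TOL:
            raise ValueError(f"{self.locus.name}: genotype frequencies sum to {total}")

    def probabilities(self) -> list[float]:
        return [self.gfreqs[g] for g in sorted(self.gfreqs, key=lambda g: g.alleles)]


def estimate_allele_frequencies(population: Population, locus: Locus) -> FrequencyTable:
    """Allele frequencies by direct gene counting.

    Each typed individual contributes two chromosomes; individuals untyped at
    the locus are excluded from the denominator.  The returned table sums to 1
    exactly (pre-rounding): frequencies are rational counts over 2 x n_typed.
    """
    counts = population.allele_counts(locus.name)
    if not counts:
        raise NoTypedIndividualsError(
            f"{locus.name}: no individual typed at this locus (monomorphic-or-empty)"
        )
    return FrequencyTable.from_counts(locus, counts)


def estimate_genotype_frequencies(
    population: Population, locus: Locus
) -> GenotypeFrequencyTable:
    """Observed genotype frequencies: count of each unordered genotype over
    the number of typed individuals."""
    counts = population.genotype_counts(locus.name)
    if not counts:
        raise NoTypedIndividualsError(
            f"{locus.name}: no individual typed at this locus (monomorphic-or-empty)"
        )
    n_typed = sum(counts.values())
    gfreqs = {g: c / n_typed for g, c in counts.items()}
    return GenotypeFrequencyTable(locus, gfreqs)


def count_alleles(freq_table: FrequencyTable) -> int:
    """Number of distinct alleles with positive frequency."""
    return freq_table.n_alleles


def exact_frequencies(counts: Mapping[AlleleName, int]) -> dict[AlleleName, Fraction]:
    """Rational allele frequencies (useful for exactness checks in reports)."""
    total = sum(counts.values())
    return {a: Fraction(c, total) for a, c in counts.items()}
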