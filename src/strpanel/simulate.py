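"""Seeded synthetic-data generators for offline testing of the pipeline.

Three generators emulate the study conditions each pipeline stage expects:

* Hardy-Weinberg populations drawn from allele-frequency tables (unlinked
  loci, random mating, optional per-locus dropout emulating hair-sample
  failure);
* Mendelian nuclear families with an optional stepwise +/-1-repeat mutation
  model (the standard STR mutation model; the default rate is 0 because the
  reference analyses assume mutation-free transmission);
* screening fixtures — annotation plus multi-sample call tables with a
  planted pass/fail composition, so filter recovery can be checked against
  ground truth.

Every generator takes a :class:`SimulationConfig` whose seed is mandatory;
identical configs reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genotypes import (
    AlleleName,
    FrequencyTable,
    Genotype,
    Individual,
    Population,
)
from .screening import MultiSampleCalls, StrAnnotation

_COMPOSITION_CLASSES = ("retain", "fail_motif", "fail_repeats", "fail_alleles")


@dataclass
class SimulationConfig:
    seed: int
    n_individuals: int = 31
    mutation_rate: float = 0.0
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("mutation_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")


def _rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(config.seed)


def simulate_population(
    freq_tables: Sequence[FrequencyTable], config: SimulationConfig
) -> Population:
    """Draw ``n_individuals`` unrelated diploids under Hardy-Weinberg.

    Each genotype is two independent draws from the locus frequency table;
    loci are independent (no linkage).  With ``dropout_rate > 0`` a genotype
    is dropped (left untyped) independently per locus per individual.
    """
    rng = _rng(config)
    n = config.n_individuals
    individuals = [Individual(f"S{i + 1:04d}") for i in range(n)]
    for table in freq_tables:
        alleles = table.alleles
        probs = np.asarray(table.probabilities())
        probs = probs / probs.sum()
        draws = rng.choice(len(alleles), size=(n, 2), p=probs)
        drop = (
            rng.random(n) < config.dropout_rate
            if config.dropout_rate > 0
            else np.zeros(n, dtype=bool)
        )
        for i, ind in enumerate(individuals):
            if drop[i]:
                continue
            ind.set_genotype(
                Genotype(table.locus.name, alleles[draws[i, 0]], alleles[draws[i, 1]])
            )
    return Population(individuals)


def _mutate(allele: AlleleName, rng: np.random.Generator) -> AlleleName:
    """Stepwise mutation: +/-1 full repeat with equal probability."""
    step = 1 if rng.random() < 0.5 else -1
    repeats = max(allele.repeats + step, 0)
    return AlleleName(repeats, allele.microvariant)


def simulate_family(
    mother: Individual,
    father: Individual,
    n_offspring: int,
    config: SimulationConfig,
    id_prefix: str = "O",
) -> list[Individual]:
    """Mendelian offspring: one uniformly chosen allele from each parent per
    locus, mutated with probability ``mutation_rate`` per transmission.

    Loci typed in only one parent leave the offspring untyped there.
    """
    rng = _rng(config)
    shared = [name for name in mother.genotypes if name in father.genotypes]
    offspring = []
    for i in range(n_offspring):
        child = Individual(f"{id_prefix}{i + 1:03d}")
        for name in shared:
            ma = mother.genotypes[name].alleles[rng.integers(0, 2)]
            pa = father.genotypes[name].alleles[rng.integers(0, 2)]
            if config.mutation_rate > 0 and rng.random() < config.mutation_rate:
                ma = _mutate(ma, rng)
            if config.mutation_rate > 0 and rng.random() < config.mutation_rate:
                pa = _mutate(pa, rng)
            child.set_genotype(Genotype(name, ma, pa))
        offspring.append(child)
    return offspring


_MOTIFS = {2: "AG", 3: "AAG", 4: "AAAG", 5: "AAAAG"}


def simulate_screening_fixture(
    n_loci: int,
    composition: dict[str, float],
    config: SimulationConfig,
    n_samples: int = 3,
) -> tuple[list[StrAnnotation], list[MultiSampleCalls], dict[str, str]]:
    """Annotation + call tables realizing a planted screening composition.

    ``composition`` maps outcome classes (``retain``, ``fail_motif``,
    ``fail_repeats``, ``fail_alleles``) to proportions summing to 1.  Class
    quotas use largest-remainder rounding so exactly ``n_loci`` loci are
    generated.  The returned truth dict maps each locus id to its intended
    class.  Demanding more distinct alleles than ``2 * n_samples`` chromosomes
    can carry is infeasible and raises ``ValueError``.
    """
    unknown = set(composition) - set(_COMPOSITION_CLASSES)
    if unknown:
        raise ValueError(f"unknown composition classes: {sorted(unknown)}")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition proportions sum to {total}, not 1")
    if 2 * n_samples < 3 and composition.get("retain", 0) > 0:
        raise ValueError(
            f"{n_samples} samples carry {2 * n_samples} chromosomes; cannot show "
            "the 3+ distinct alleles the retain class requires"
        )
    # largest-remainder apportionment of n_loci among classes
    quotas = {k: composition[k] * n_loci for k in composition}
    counts = {k: math.floor(q) for k, q in quotas.items()}
    short = n_loci - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1

    rng = _rng(config)
    sample_ids = [f"R{i + 1}" for i in range(n_samples)]
    annotations: list[StrAnnotation] = []
    calls: list[MultiSampleCalls] = []
    truth: dict[str, str] = {}
    idx = 0
    for klass in _COMPOSITION_CLASSES:
        for _ in range(counts.get(klass, 0)):
            idx += 1
            locus_id = f"SYN{idx:05d}"
            motif_len = int(rng.choice([4, 5]))
            ref_repeats = float(rng.integers(10, 21))
            n_alleles = int(rng.integers(3, min(6, 2 * n_samples) + 1))
            if klass == "fail_motif":
                motif_len = int(rng.choice([2, 3]))
            elif klass == "fail_repeats":
                ref_repeats = float(rng.choice([rng.integers(3, 10), rng.integers(21, 40)]))
            elif klass == "fail_alleles":
                n_alleles = int(rng.integers(1, 3))
            annotations.append(
                StrAnnotation(
                    locus_id=locus_id,
                    scaffold=f"scaffold{int(rng.integers(1, 100000))}",
                    position=int(rng.integers(1, 10_000_000)),
                    motif=_MOTIFS[motif_len],
                    ref_repeat_count=ref_repeats,
                )
            )
            # draw chromosome alleles guaranteeing exactly n_alleles distinct
            base = int(ref_repeats)
            allele_pool = [float(base + d) for d in range(n_alleles)]
            chroms = list(allele_pool)
            while len(chroms) < 2 * n_samples:
                chroms.append(float(rng.choice(allele_pool)))
            chroms = [chroms[i] for i in rng.permutation(len(chroms))]
            call = MultiSampleCalls(locus_id)
            for s, sid in enumerate(sample_ids):
                call.calls[sid] = (chroms[2 * s], chroms[2 * s + 1])
            calls.append(call)
            truth[locus_id] = klass
    order = rng.permutation(len(annotations))
    annotations = [annotations[i] for i in order]
    calls = [calls[i] for i in order]
    return annotations, calls, truth
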