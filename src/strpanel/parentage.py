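"""Mendelian exclusion parentage testing, pedigree reconstruction, sex calling.

A putative parent is *excluded* at a locus when no assignment of the child's
alleles to the parents is consistent with Mendelian transmission.  Verdicts
aggregate exclusions across loci against a configurable threshold (default 0:
a single incompatible locus excludes, appropriate when mutation and drop-out
are assumed absent; raise it to tolerate occasional mutations, at the cost of
discriminating power).

Sex is called from amelogenin-style fragment lengths: the Y-linked copy of
the locus carries a deletion, so males show two fragment lengths (X and Y)
and females one (X only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

from .genotypes import (
    FrequencyTable,
    Genotype,
    Individual,
    LocusMismatchError,
    Population,
)

COMPATIBLE = "compatible"
EXCLUDED = "excluded"
UNTYPED = "untyped"

#: Default amelogenin fragment lengths (bp): X-linked and deletion-carrying Y.
X_FRAGMENT_BP = 109
Y_FRAGMENT_BP = 87


def duo_compatible(child: Genotype, parent: Genotype) -> str:
    """Single-parent check: compatible iff child and parent share an allele."""
    if child.locus != parent.locus:
        raise LocusMismatchError(f"{child.locus} vs {parent.locus}")
    shared = set(child.alleles) & set(parent.alleles)
    return COMPATIBLE if shared else EXCLUDED


def trio_compatible(child: Genotype, mother: Genotype, father: Genotype) -> str:
    """Two-parent check: compatible iff one child allele can come from the
    mother and the other from the father."""
    if not (child.locus == mother.locus == father.locus):
        raise LocusMismatchError(
            f"{child.locus} vs {mother.locus} vs {father.locus}"
        )
    c1, c2 = child.alleles
    m = set(mother.alleles)
    f = set(father.alleles)
    ok = (c1 in m and c2 in f) or (c2 in m and c1 in f)
    return COMPATIBLE if ok else EXCLUDED


@dataclass
class CompatibilityResult:
    """Per-candidate (or candidate-pair) Mendelian screening summary."""

    child_id: str
    mother_id: Optional[str]
    father_id: Optional[str]
    per_locus: dict[str, str] = field(default_factory=dict)
    untestable: bool = False

    @property
    def n_exclusions(self) -> int:
        return sum(1 for v in self.per_locus.values() if v == EXCLUDED)

    @property
    def n_informative(self) -> int:
        return sum(1 for v in self.per_locus.values() if v != UNTYPED)

    def verdict(self, exclusion_threshold: int = 0) -> str:
        return EXCLUDED if self.n_exclusions > exclusion_threshold else "consistent"


def _evaluate_pair(
    child: Individual,
    mother: Optional[Individual],
    father: Optional[Individual],
    loci: Iterable[str],
) -> CompatibilityResult:
    res = CompatibilityResult(
        child_id=child.id,
        mother_id=mother.id if mother else None,
        father_id=father.id if father else None,
    )
    for name in loci:
        cg = child.genotypes.get(name)
        mg = mother.genotypes.get(name) if mother else None
        fg = father.genotypes.get(name) if father else None
        if cg is None or (mother and mg is None) or (father and fg is None):
            res.per_locus[name] = UNTYPED
        elif mother and father:
            res.per_locus[name] = trio_compatible(cg, mg, fg)
        elif mother:
            res.per_locus[name] = duo_compatible(cg, mg)
        else:
            res.per_locus[name] = duo_compatible(cg, fg)
    if res.n_informative == 0:
        res.untestable = True
    return res


def assign_parents(
    child: Individual,
    candidate_mothers: Sequence[Individual],
    candidate_fathers: Sequence[Individual],
    loci: Sequence[str],
    exclusion_threshold: int = 0,
) -> list[CompatibilityResult]:
    """Evaluate all mother x father candidate pairs for one offspring.

    When one candidate list is empty the other side is tested as single-parent
    duos.  Results are sorted by (n_exclusions ascending, n_informative
    descending); pairs sharing no typed locus with the child are flagged
    untestable rather than dropped.
    """
    results: list[CompatibilityResult] = []
    if candidate_mothers and candidate_fathers:
        for m, f in product(candidate_mothers, candidate_fathers):
            if m.id == f.id:
                continue
            results.append(_evaluate_pair(child, m, f, loci))
    elif candidate_mothers:
        for m in candidate_mothers:
            results.append(_evaluate_pair(child, m, None, loci))
    elif candidate_fathers:
        for f in candidate_fathers:
            results.append(_evaluate_pair(child, None, f, loci))
    results.sort(key=lambda r: (r.n_exclusions, -r.n_informative))
    return results


@dataclass
class PedigreeAssignment:
    """Reconstructed families: (mother, father) -> children, plus unassigned
    offspring with a reason code."""

    families: list[tuple[Optional[str], Optional[str], list[str]]]
    unassigned: list[tuple[str, str]]  # (offspring id, reason)


def reconstruct_pedigree(
    cohort: Population,
    adult_ids: Iterable[str],
    offspring_ids: Iterable[str],
    loci: Sequence[str],
    exclusion_threshold: int = 0,
) -> PedigreeAssignment:
    """Assign each offspring its unique consistent adult pair, conservatively.

    All unordered adult pairs are screened per offspring; an offspring is
    assigned only when exactly one pair has at most ``exclusion_threshold``
    Mendelian exclusions.  Offspring with no consistent pair, with several
    (ambiguous), or typed at no locus are left unassigned with a reason code.
    Adults may head multiple families (a shared sire links families).  When
    adult sexes are known (``sex_call``), the female is reported as mother;
    otherwise pair orientation follows id order.
    """
    adult_ids = list(adult_ids)
    offspring_ids = list(offspring_ids)
    if set(adult_ids) & set(offspring_ids):
        raise ValueError("adult and offspring id sets must be disjoint")
    index = {ind.id: ind for ind in cohort.individuals}
    adults = [index[a] for a in adult_ids]
    fam: dict[tuple[Optional[str], Optional[str]], list[str]] = {}
    unassigned: list[tuple[str, str]] = []
    for oid in offspring_ids:
        child = index[oid]
        if not any(name in child.genotypes for name in loci):
            unassigned.append((oid, "untyped"))
            continue
        consistent = []
        for i in range(len(adults)):
            for j in range(i + 1, len(adults)):
                a, b = adults[i], adults[j]
                if a.sex_call == "XY" and b.sex_call != "XY":
                    mother, father = b, a
                elif b.sex_call == "XY" and a.sex_call != "XY":
                    mother, father = a, b
                elif a.sex_call == b.sex_call == "XY":
                    continue  # two males cannot form a parent pair
                else:
                    mother, father = sorted((a, b), key=lambda x: x.id)
                res = _evaluate_pair(child, mother, father, loci)
                if res.untestable:
                    continue
                if res.n_exclusions <= exclusion_threshold:
                    consistent.append(res)
        if len(consistent) == 1:
            key = (consistent[0].mother_id, consistent[0].father_id)
            fam.setdefault(key, []).append(oid)
        elif len(consistent) == 0:
            unassigned.append((oid, "no_consistent_pair"))
        else:
            unassigned.append((oid, "ambiguous"))
    families = [(m, f, kids) for (m, f), kids in fam.items()]
    return PedigreeAssignment(families=families, unassigned=unassigned)


@dataclass(frozen=True)
class SexCall:
    individual_id: str
    fragments_bp: frozenset
    call: str  # "XX", "XY" or "unknown"


def call_sex(
    fragments_bp: Iterable[float],
    individual_id: str = "",
    x_len: int = X_FRAGMENT_BP,
    y_len: int = Y_FRAGMENT_BP,
    tol_bp: float = 2.0,
) -> SexCall:
    """Sex from amelogenin fragment lengths.

    XY iff fragments match both the X and the Y length within ``tol_bp``;
    XX iff only the X length matches; anything else (including a lone
    Y-length fragment or no fragments) is unknown.  The default 2 bp
    tolerance absorbs electrophoretic sizing jitter.
    """
    frags = frozenset(fragments_bp)
    has_x = any(abs(f - x_len) <= tol_bp for f in frags)
    has_y = any(abs(f - y_len) <= tol_bp for f in frags)
    if has_x and has_y:
        call = "XY"
    elif has_x:
        call = "XX"
    else:
        call = "unknown"
    return SexCall(individual_id, frags, call)


# ---------------------------------------------------------------------------
# Vectorized Monte-Carlo exclusion experiments (shared by tests/validation)

def _encode_table(table: FrequencyTable) -> np.ndarray:
    return np.asarray(table.probabilities(), dtype=float)


def _draw(rng: np.random.Generator, probs: np.ndarray, size) -> np.ndarray:
    return rng.choice(len(probs), size=size, p=probs / probs.sum())


def false_inclusion_trials(
    tables: Sequence[FrequencyTable],
    n_trials: int,
    seed: int,
    scenario: str = "couple",
) -> int:
    """Count non-excluded random non-parents across a panel, by simulation.

    Each trial simulates a Hardy-Weinberg family at every locus and screens a
    random unrelated candidate: scenario ``"couple"`` tests a random
    male+female pair as the child's parents; ``"mother_known"`` tests a random
    male against the true mother-child pair.  Returns the number of trials in
    which the candidate was compatible at every locus (a false inclusion).
    """
    if scenario not in ("couple", "mother_known"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    included = np.ones(n_trials, dtype=bool)
    for table in tables:
        probs = _encode_table(table)
        m1, m2, f1 = (_draw(rng, probs, n_trials) for _ in range(3))
        pick = rng.integers(0, 2, n_trials)
        c_mat = np.where(pick == 0, m1, m2)  # maternal allele
        c_pat = f1  # paternal allele from the true father
        x1, x2 = _draw(rng, probs, n_trials), _draw(rng, probs, n_trials)
        if scenario == "mother_known":
            # trio with the true mother and the candidate male
            mhas_c1 = (m1 == c_mat) | (m2 == c_mat)
            mhas_c2 = (m1 == c_pat) | (m2 == c_pat)
            xhas_c1 = (x1 == c_mat) | (x2 == c_mat)
            xhas_c2 = (x1 == c_pat) | (x2 == c_pat)
            ok = (mhas_c1 & xhas_c2) | (mhas_c2 & xhas_c1)
        else:
            # random couple (both unrelated) claimed as the parent pair
            y1, y2 = _draw(rng, probs, n_trials), _draw(rng, probs, n_trials)
            xhas_c1 = (x1 == c_mat) | (x2 == c_mat)
            xhas_c2 = (x1 == c_pat) | (x2 == c_pat)
            yhas_c1 = (y1 == c_mat) | (y2 == c_mat)
            yhas_c2 = (y1 == c_pat) | (y2 == c_pat)
            ok = (xhas_c1 & yhas_c2) | (xhas_c2 & yhas_c1)
        included &= ok
    return int(included.sum())


def mother_known_exclusion_rate(
    table: FrequencyTable, n_trials: int, seed: int
) -> float:
    """Single-locus Monte-Carlo exclusion rate of random non-fathers tested
    against mother-child pairs (the scenario the no-1/2 PE formula models)."""
    incl = false_inclusion_trials([table], n_trials, seed, scenario="mother_known")
    return 1.0 - incl / n_trials
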