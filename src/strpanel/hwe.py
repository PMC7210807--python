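"""Hardy-Weinberg equilibrium exact test for multi-allelic STR loci.

The test conditions on the observed allele counts.  Under the null of random
mating, the probability of a genotype array (the symmetric matrix of genotype
counts ``n_ij``) given allele counts ``c_1..c_k`` with ``sum c_i = 2n`` is

    P(array) = n! * 2^h / prod_{i<=j} n_ij!  *  prod_i c_i! / (2n)!

where ``h`` is the number of heterozygous individuals (Levene's conditional
distribution).  The p-value is the total probability of all arrays with the
same allele counts whose probability is at or below the observed array's
("probability test" ordering, the default style of the classic exact-test
implementations).

Small array spaces are fully enumerated; larger ones are sampled by Monte
Carlo: random pairings of the 2n allele copies, which draws arrays exactly
from the conditional null.  The Monte Carlo path requires an explicit seed so
results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .genotypes import Genotype, Locus, Population, StrPanelError

_LOG_TOL = 1e-9  # relative tolerance when comparing array log-probabilities


class SeedRequiredError(StrPanelError):
    """Monte-Carlo sampling was needed but no seed was supplied."""


@dataclass
class HWEResult:
    locus: Optional[Locus]
    p_value: Optional[float]
    n_typed: int
    method: str  # "enumeration", "monte_carlo" or "none"
    flag: str  # "D" (departure, p < alpha), "NS", "NA" (untestable)
    mc_reps: Optional[int] = None
    seed: Optional[int] = None


def _array_logprob_rel(matrix_counts: Sequence[int], n_het: int) -> float:
    """Log-probability of an array up to the constant shared by all arrays
    with the same allele counts: h*log2 - sum log(n_ij!)."""
    return n_het * math.log(2.0) - sum(math.lgamma(c + 1) for c in matrix_counts)


def _enumerate_arrays(allele_counts: Sequence[int], max_configs: int):
    """Yield (het_counts, diag_counts) for every genotype array consistent with
    the allele counts.  het_counts is the flat list over pairs i<j.

    Returns None (via StopIteration semantics) by raising _TooMany when more
    than ``max_configs`` arrays exist.
    """
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    het = [0] * len(pairs)
    remaining = list(allele_counts)
    results_seen = 0

    def rec(idx: int):
        nonlocal results_seen
        if idx == len(pairs):
            diag = []
            for c in remaining:
                if c % 2:
                    return
                diag.append(c // 2)
            results_seen += 1
            if results_seen > max_configs:
                raise _TooManyConfigs
            yield het.copy(), diag
            return
        i, j = pairs[idx]
        limit = min(remaining[i], remaining[j])
        for h in range(limit + 1):
            het[idx] = h
            remaining[i] -= h
            remaining[j] -= h
            yield from rec(idx + 1)
            remaining[i] += h
            remaining[j] += h
        het[idx] = 0

    yield from rec(0)


class _TooManyConfigs(Exception):
    pass


def _observed_from_counts(genotype_counts: Mapping[Genotype, int]):
    """Index alleles and build the observed het/diag configuration."""
    alleles = sorted({a for g in genotype_counts for a in g.alleles})
    index = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    diag = [0] * k
    het = {}
    allele_counts = [0] * k
    n = 0
    n_het = 0
    for g, c in genotype_counts.items():
        if c < 0:
            raise ValueError("negative genotype count")
        if c == 0:
            continue
        n += c
        i, j = index[g.a1], index[g.a2]
        allele_counts[i] += c
        allele_counts[j] += c
        if i == j:
            diag[i] += c
        else:
            het[(i, j)] = het.get((i, j), 0) + c
            n_het += c
    return alleles, allele_counts, diag, het, n, n_het


def hwe_exact_test(
    genotype_counts: Mapping[Genotype, int],
    mc_reps: int = 100_000,
    seed: Optional[int] = None,
    max_enum_configs: int = 1_000_000,
    alpha: float = 0.05,
    locus: Optional[Locus] = None,
) -> HWEResult:
    """Exact conditional HWE test on one locus's genotype counts.

    ``mc_reps=0`` forces full enumeration (raises if the array space exceeds
    ``max_enum_configs``).  Monomorphic or empty loci are untestable and
    return flag ``NA``.
    """
    alleles, allele_counts, diag, het, n, _ = _observed_from_counts(genotype_counts)
    if n == 0 or len([c for c in allele_counts if c > 0]) < 2:
        return HWEResult(locus, None, n, "none", "NA")

    k = len(alleles)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    obs_matrix = [het.get(p, 0) for p in pairs] + diag
    obs_nhet = sum(het.values())
    obs_lp = _array_logprob_rel(obs_matrix, obs_nhet)

    # --- full enumeration when the array space is small enough
    try:
        lps: list[float] = []
        extreme: list[bool] = []
        for het_cfg, diag_cfg in _enumerate_arrays(allele_counts, max_enum_configs):
            nh = sum(het_cfg)
            lp = _array_logprob_rel(het_cfg + diag_cfg, nh)
            lps.append(lp)
            extreme.append(lp <= obs_lp + _LOG_TOL * max(1.0, abs(obs_lp)))
        arr = np.asarray(lps)
        shift = arr.max()
        weights = np.exp(arr - shift)
        p = float(weights[np.asarray(extreme)].sum() / weights.sum())
        return HWEResult(locus, min(p, 1.0), n, "enumeration", "D" if p < alpha else "NS")
    except _TooManyConfigs:
        if mc_reps == 0:
            raise StrPanelError(
                "array space too large for full enumeration; increase "
                "max_enum_configs or allow Monte Carlo (mc_reps > 0)"
            )

    # --- Monte Carlo: random pairings of the 2n allele copies
    if seed is None:
        raise SeedRequiredError(
            "Monte-Carlo HWE sampling requires an explicit seed for reproducibility"
        )
    p = _mc_pvalue(np.asarray(allele_counts), obs_lp, mc_reps, seed)
    return HWEResult(
        locus, p, n, "monte_carlo", "D" if p < alpha else "NS", mc_reps=mc_reps, seed=seed
    )


def _mc_pvalue(
    allele_counts: np.ndarray, obs_lp: float, reps: int, seed: int, chunk: int = 20_000
) -> float:
    """Monte-Carlo p-value: fraction of random pairings whose conditional
    array probability is at or below the observed one."""
    rng = np.random.default_rng(seed)
    k = len(allele_counts)
    pool = np.repeat(np.arange(k), allele_counts)
    two_n = pool.size
    n_pairs = two_n // 2
    ncodes = k * k
    log2 = math.log(2.0)
    hits = 0
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        keys = rng.random((m, two_n))
        order = np.argsort(keys, axis=1, kind="stable")
        arr = pool[order]
        a = arr[:, 0 : 2 * n_pairs : 2]
        b = arr[:, 1 : 2 * n_pairs : 2]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        codes = lo * k + hi
        nhet = (a != b).sum(axis=1)
        offset = (np.arange(m) * ncodes)[:, None]
        counts = np.bincount((codes + offset).ravel(), minlength=m * ncodes).reshape(
            m, ncodes
        )
        lp = nhet * log2 - gammaln(counts + 1.0).sum(axis=1)
        hits += int((lp <= obs_lp + _LOG_TOL * max(1.0, abs(obs_lp))).sum())
        done += m
    return hits / reps


def hwe_panel(
    population: Population,
    loci: Sequence[Locus],
    mc_reps: int = 100_000,
    seed: Optional[int] = None,
    max_enum_configs: int = 1_000_000,
    alpha: float = 0.05,
) -> list[HWEResult]:
    """Run the exact test at each panel locus, with one derived sub-seed per
    locus so the panel is reproducible from a single seed."""
    sub_seeds: list[Optional[int]]
    if seed is not None:
        state = np.random.SeedSequence(seed).generate_state(max(len(loci), 1))
        sub_seeds = [int(s % (2**31)) for s in state]
    else:
        sub_seeds = [None] * len(loci)
    results = []
    for locus, sub in zip(loci, sub_seeds):
        counts = population.genotype_counts(locus.name)
        results.append(
            hwe_exact_test(
                counts,
                mc_reps=mc_reps,
                seed=sub,
                max_enum_configs=max_enum_configs,
                alpha=alpha,
                locus=locus,
            )
        )
    return results
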