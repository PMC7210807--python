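"""Forensic panel statistics for STR parentage systems.

Per-locus measures
------------------
* expected heterozygosity  He = 1 - sum_i p_i^2
* probability of exclusion PE = sum_i p_i (1-p_i)^2
                               - 1/2 sum_{i<j} p_i^2 p_j^2 (4 - 3 p_i - 3 p_j)
* discrimination power     DP = 1 - sum_i g_i^2   (g_i = genotype frequencies)

Panel (cumulative) measures combine loci multiplicatively:
CPE = 1 - prod_k (1 - PE_k) and TDP = 1 - prod_k (1 - DP_k).

The PE convention above is the one used in published multiplex-panel
characterizations of this kind (it carries a 1/2 factor on the unordered-pair
sum).  The classical known-mother exclusion probability — the chance that a
random unrelated male is Mendelian-incompatible with a mother–child pair —
omits that 1/2 and is provided separately as
:func:`exclusion_probability_mother_known`; see docs/methods.md for the
simulation evidence distinguishing the two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .genotypes import (
    FrequencyTable,
    GenotypeFrequencyTable,
    Locus,
    Population,
    estimate_allele_frequencies,
    estimate_genotype_frequencies,
)


def expected_heterozygosity(freqs: FrequencyTable) -> float:
    """Gene diversity 1 - sum p_i^2."""
    return 1.0 - sum(p * p for p in freqs.freqs.values())


def probability_of_exclusion(freqs: FrequencyTable) -> float:
    """Per-locus probability of exclusion, panel-publication convention.

    PE = sum_i p_i (1-p_i)^2 - 1/2 sum_{i<j} p_i^2 p_j^2 (4 - 3 p_i - 3 p_j).
    """
    p = freqs.probabilities()
    single = sum(x * (1.0 - x) ** 2 for x in p)
    pair = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            pair += p[i] ** 2 * p[j] ** 2 * (4.0 - 3.0 * p[i] - 3.0 * p[j])
    return single - 0.5 * pair


def exclusion_probability_mother_known(freqs: FrequencyTable) -> float:
    """Probability that a random non-father is excluded given the mother.

    The Jamieson-style formula without the 1/2 pair factor:
    sum_i p_i (1-p_i)^2 - sum_{i<j} p_i^2 p_j^2 (4 - 3 p_i - 3 p_j).
    Equals the exact Mendelian exclusion rate of a random unrelated male
    tested against a mother-child pair drawn under Hardy-Weinberg.
    """
    p = freqs.probabilities()
    single = sum(x * (1.0 - x) ** 2 for x in p)
    pair = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            pair += p[i] ** 2 * p[j] ** 2 * (4.0 - 3.0 * p[i] - 3.0 * p[j])
    return single - pair


def discrimination_power(gfreqs: GenotypeFrequencyTable) -> float:
    """Probability that two random individuals differ in genotype: 1 - sum g_i^2."""
    return 1.0 - sum(g * g for g in gfreqs.gfreqs.values())


def _cumulative(values: Sequence[float], what: str) -> float:
    if len(values) == 0:
        raise ValueError(f"cannot combine an empty list of {what} values")
    prod = 1.0
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{what} value out of [0,1]: {v}")
        prod *= 1.0 - v
    return 1.0 - prod


def cumulative_exclusion(pe_values: Sequence[float]) -> float:
    """CPE = 1 - prod_k (1 - PE_k)."""
    return _cumulative(pe_values, "PE")


def cumulative_discrimination(dp_values: Sequence[float]) -> float:
    """TDP = 1 - prod_k (1 - DP_k)."""
    return _cumulative(dp_values, "DP")


def format_cumulative(value: float, max_decimals: int = 15) -> str:
    """Render a cumulative probability with enough decimals to show its
    departure from 1 (e.g. ``0.999999472``), 4 decimals minimum.

    This reproduces the variable-precision convention of published panel
    characterization tables.
    """
    if value >= 1.0:
        return "1"
    decimals = max(4, min(max_decimals, math.ceil(-math.log10(1.0 - value)) + 2))
    return f"{value:.{decimals}f}"


@dataclass
class LocusStats:
    """One report row: per-locus statistics plus running cumulative columns."""

    locus: Locus
    n_alleles: int
    He: float
    PE: float
    cum_PE: float
    DP: Optional[float] = None
    cum_DP: Optional[float] = None
    hwe_p: Optional[float] = None
    hwe_flag: Optional[str] = None


@dataclass
class PanelReport:
    """Panel characterization: ordered per-locus rows plus panel summaries."""

    rows: list[LocusStats]

    @property
    def mean_alleles(self) -> float:
        return sum(r.n_alleles for r in self.rows) / len(self.rows)

    @property
    def mean_He(self) -> float:
        return sum(r.He for r in self.rows) / len(self.rows)

    @property
    def mean_PE(self) -> float:
        return sum(r.PE for r in self.rows) / len(self.rows)

    @property
    def mean_DP(self) -> Optional[float]:
        if any(r.DP is None for r in self.rows):
            return None
        return sum(r.DP for r in self.rows) / len(self.rows)

    @property
    def CPE(self) -> float:
        return self.rows[-1].cum_PE

    @property
    def TDP(self) -> Optional[float]:
        return self.rows[-1].cum_DP

    def to_dataframe(self):
        import pandas as pd

        records = []
        for r in self.rows:
            records.append(
                {
                    "locus": r.locus.name,
                    "n_alleles": r.n_alleles,
                    "He": r.He,
                    "HWE": r.hwe_flag,
                    "hwe_p": r.hwe_p,
                    "PE": r.PE,
                    "CPE": r.cum_PE,
                    "DP": r.DP,
                    "TDP": r.cum_DP,
                }
            )
        return pd.DataFrame.from_records(records)

    def to_text(self) -> str:
        """Aligned text report; per-locus values at 4 decimals, cumulative
        columns at adaptive precision."""
        headers = ["Locus", "k", "He", "HWE", "PE", "CPE", "DP", "TDP"]
        lines = []
        for r in self.rows:
            lines.append(
                [
                    r.locus.name,
                    str(r.n_alleles),
                    f"{r.He:.4f}",
                    r.hwe_flag or "-",
                    f"{r.PE:.4f}",
                    format_cumulative(r.cum_PE),
                    "-" if r.DP is None else f"{r.DP:.4f}",
                    "-" if r.cum_DP is None else format_cumulative(r.cum_DP),
                ]
            )
        mean_row = [
            "Mean",
            f"{self.mean_alleles:.4f}",
            f"{self.mean_He:.4f}",
            "",
            f"{self.mean_PE:.4f}",
            "",
            "-" if self.mean_DP is None else f"{self.mean_DP:.4f}",
            "",
        ]
        lines.append(mean_row)
        widths = [max(len(h), *(len(row[i]) for row in lines)) for i, h in enumerate(headers)]
        out = ["  ".join(h.ljust(w) for h, w in zip(headers, widths))]
        for row in lines:
            out.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
        return "\n".join(out)


def panel_report_from_frequencies(tables: Sequence[FrequencyTable]) -> PanelReport:
    """He/PE/CPE characterization directly from allele-frequency tables.

    Discrimination power needs observed genotype frequencies and is left blank
    here; use :func:`panel_report` with a genotyped population for it.
    """
    if not tables:
        raise ValueError("no frequency tables supplied")
    rows: list[LocusStats] = []
    running = 1.0
    for t in tables:
        pe = probability_of_exclusion(t)
        running *= 1.0 - pe
        rows.append(
            LocusStats(
                locus=t.locus,
                n_alleles=t.n_alleles,
                He=expected_heterozygosity(t),
                PE=pe,
                cum_PE=1.0 - running,
            )
        )
    return PanelReport(rows)


def panel_report(
    population: Population,
    loci: Sequence[Locus],
    hwe: bool = False,
    mc_reps: int = 100_000,
    seed: Optional[int] = None,
) -> PanelReport:
    """Full panel characterization from a genotyped population.

    Allele and genotype frequencies are estimated per locus (each locus uses
    its own typed-individual denominator); cumulative columns accumulate in
    the given locus order.  With ``hwe=True`` a Hardy-Weinberg exact test is
    run per locus (see :mod:`strpanel.hwe`).
    """
    from .genotypes import NoTypedIndividualsError

    rows: list[LocusStats] = []
    run_pe = 1.0
    run_dp = 1.0
    hwe_results = None
    if hwe:
        from .hwe import hwe_panel

        hwe_results = hwe_panel(population, loci, mc_reps=mc_reps, seed=seed)
    for idx, locus in enumerate(loci):
        try:
            ft = estimate_allele_frequencies(population, locus)
            gt = estimate_genotype_frequencies(population, locus)
        except NoTypedIndividualsError as exc:
            raise NoTypedIndividualsError(f"panel report: {exc}") from exc
        pe = probability_of_exclusion(ft)
        dp = discrimination_power(gt)
        run_pe *= 1.0 - pe
        run_dp *= 1.0 - dp
        row = LocusStats(
            locus=locus,
            n_alleles=ft.n_alleles,
            He=expected_heterozygosity(ft),
            PE=pe,
            cum_PE=1.0 - run_pe,
            DP=dp,
            cum_DP=1.0 - run_dp,
        )
        if hwe_results is not None:
            row.hwe_p = hwe_results[idx].p_value
            row.hwe_flag = hwe_results[idx].flag
        rows.append(row)
    return PanelReport(rows)
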