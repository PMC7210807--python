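"""Forensic panel statistics: He, PE, DP and their cumulative panel versions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strpanel import (
    AlleleName,
    FrequencyTable,
    Genotype,
    GenotypeFrequencyTable,
    Locus,
    cumulative_discrimination,
    cumulative_exclusion,
    discrimination_power,
    exclusion_probability_mother_known,
    expected_heterozygosity,
    format_cumulative,
    mother_known_exclusion_rate,
    panel_report_from_frequencies,
    probability_of_exclusion,
)

A = AlleleName

# Published per-locus characterization of the reference panel (4-dp values).
PUBLISHED = {
    "DA3S1123": (0.7040, 0.4818),
    "DA2S1059": (0.6878, 0.4646),
    "DB1S1259": (0.8902, 0.7856),
    "DD3S86": (0.7263, 0.5385),
    "DE1S613": (0.8366, 0.6929),
    "DF1S579": (0.8626, 0.7346),
    "DA2S1575": (0.8127, 0.6521),
    "DF2S497": (0.6852, 0.4622),
    "DA3S1145": (0.7627, 0.5648),
    "DD2S793": (0.7638, 0.5640),
    "DD4S705": (0.8783, 0.7643),
    "DB1S542": (0.6993, 0.4817),
    "DA1S1290": (0.8325, 0.6804),
    "DA1S1470": (0.7794, 0.5971),
    "DC1S1364": (0.7617, 0.5774),
}


def table(probs):
    freqs = {A(10 + i): p for i, p in enumerate(probs)}
    return FrequencyTable(Locus("T"), freqs)


def pe_ordered_oracle(probs):
    """Independent evaluation of the exclusion formula with the pair term
    written as a quarter of the full ordered double loop."""
    single = sum(p * (1 - p) ** 2 for p in probs)
    ordered = 0.0
    for i, pi in enumerate(probs):
        for j, pj in enumerate(probs):
            if i != j:
                ordered += pi**2 * pj**2 * (4 - 3 * pi - 3 * pj)
    return single - 0.25 * ordered


simplexes = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=8
).map(lambda xs: [x / sum(xs) for x in xs])


class TestExpectedHeterozygosity:
    @pytest.mark.parametrize("name", sorted(PUBLISHED))
    def test_reference_panel_matches_published_4dp(self, name, reference_tables):
        t = {t.locus.name: t for t in reference_tables}[name]
        assert round(expected_heterozygosity(t), 4) == PUBLISHED[name][0]

    def test_degenerate_and_symmetric(self):
        assert expected_heterozygosity(table([1.0])) == 0.0
        assert expected_heterozygosity(table([0.5, 0.5])) == pytest.approx(0.5)

    @given(simplexes)
    def test_bounded_on_simplex(self, probs):
        he = expected_heterozygosity(table(probs))
        assert -1e-12 <= he <= 1.0


class TestProbabilityOfExclusion:
    @pytest.mark.parametrize("name", sorted(PUBLISHED))
    def test_reference_panel_matches_published_4dp(self, name, reference_tables):
        t = {t.locus.name: t for t in reference_tables}[name]
        assert round(probability_of_exclusion(t), 4) == PUBLISHED[name][1]

    def test_single_allele_gives_zero(self):
        assert probability_of_exclusion(table([1.0])) == pytest.approx(0.0)

    def test_biallelic_half_half(self):
        # hand evaluation: 2*0.5*0.25 - 0.5 * [0.25*0.25*(4-1.5-1.5)] = 0.21875
        assert probability_of_exclusion(table([0.5, 0.5])) == pytest.approx(0.21875)

    @given(simplexes)
    def test_matches_independent_ordered_loop_evaluation(self, probs):
        assert probability_of_exclusion(table(probs)) == pytest.approx(
            pe_ordered_oracle(probs), abs=1e-12
        )

    @given(simplexes)
    def test_bounded_on_simplex(self, probs):
        assert -1e-12 <= probability_of_exclusion(table(probs)) <= 1.0


class TestMotherKnownExclusion:
    """The pair-sum variant without the 1/2 factor is the exact probability
    that a random male is Mendelian-excluded against a mother-child pair."""

    @staticmethod
    def exact_exclusion_by_enumeration(probs):
        k = len(probs)
        excluded = 0.0
        for m in itertools.product(range(k), repeat=2):
            wm = probs[m[0]] * probs[m[1]]
            for pat in range(k):  # paternal allele from the HW gene pool
                for cm in m:  # maternal allele
                    child = (cm, pat)
                    w = wm * probs[pat] * 0.5
                    for am in itertools.product(range(k), repeat=2):
                        ok = (child[0] in m and child[1] in am) or (
                            child[1] in m and child[0] in am
                        )
                        if not ok:
                            excluded += w * probs[am[0]] * probs[am[1]]
        return excluded

    @pytest.mark.parametrize(
        "probs", [[0.5, 0.5], [0.7, 0.2, 0.1], [0.4, 0.3, 0.2, 0.1]]
    )
    def test_formula_equals_exhaustive_enumeration(self, probs):
        expected = self.exact_exclusion_by_enumeration(probs)
        assert exclusion_probability_mother_known(table(probs)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_monte_carlo_trios_agree_with_formula(self, reference_tables):
        # 200k simulated mother-child pairs + random non-fathers at one locus
        t = reference_tables[0]  # DA3S1123, 5 alleles
        n = 200_000
        rate = mother_known_exclusion_rate(t, n_trials=n, seed=20260923)
        expected = exclusion_probability_mother_known(t)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(rate - expected) <= 3 * se

    def test_published_convention_larger_than_mother_known(self, reference_tables):
        for t in reference_tables:
            assert probability_of_exclusion(t) > exclusion_probability_mother_known(t)


class TestDiscriminationPower:
    def gtable(self, gprobs):
        gfreqs = {
            Genotype("T", A(10 + i), A(10 + i)): p for i, p in enumerate(gprobs)
        }
        return GenotypeFrequencyTable(Locus("T"), gfreqs)

    def test_examples(self):
        assert discrimination_power(self.gtable([1.0])) == 0.0
        assert discrimination_power(self.gtable([0.25] * 4)) == pytest.approx(0.75)
        assert discrimination_power(self.gtable([0.5, 0.25, 0.25])) == pytest.approx(0.625)

    @given(
        st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=1, max_size=5).map(
            lambda xs: [x / sum(xs) for x in xs]
        )
    )
    def test_equals_two_draw_mismatch_enumeration(self, gprobs):
        # P(two independent draws differ), enumerated over all genotype pairs
        mismatch = sum(
            gi * gj
            for i, gi in enumerate(gprobs)
            for j, gj in enumerate(gprobs)
            if i != j
        )
        assert discrimination_power(self.gtable(gprobs)) == pytest.approx(
            mismatch, abs=1e-12
        )


class TestCumulativeOperators:
    def test_two_locus_exclusion_example(self):
        assert round(cumulative_exclusion([0.4818, 0.4646]), 4) == 0.7226

    def test_identity_on_single_locus(self):
        assert cumulative_exclusion([0.4818]) == pytest.approx(0.4818)
        assert cumulative_discrimination([0.83]) == pytest.approx(0.83)

    def test_half_half(self):
        assert cumulative_discrimination([0.5, 0.5]) == pytest.approx(0.75)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cumulative_exclusion([])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_permutation_invariant_and_monotone(self, values):
        base = cumulative_exclusion(values)
        assert cumulative_exclusion(values[::-1]) == pytest.approx(base, abs=1e-12)
        assert cumulative_exclusion(values + [0.3]) >= base - 1e-12
        assert base >= max(values) - 1e-12

    def test_all_zero_effect(self):
        assert cumulative_exclusion([0.0, 0.0]) == 0.0


class TestPanelReport:
    def test_reference_panel_summaries(self, reference_tables):
        rep = panel_report_from_frequencies(reference_tables)
        assert round(rep.mean_alleles, 4) == 7.3333
        assert round(rep.mean_He, 4) == 0.7789
        assert round(rep.mean_PE, 4) == 0.6028
        assert rep.CPE == pytest.approx(0.999999472, abs=1e-8)
        assert round(rep.rows[1].cum_PE, 4) == 0.7226

    def test_single_locus_panel(self, reference_tables):
        rep = panel_report_from_frequencies(reference_tables[:1])
        assert rep.CPE == pytest.approx(rep.rows[0].PE)

    def test_permuting_locus_order_keeps_final_cpe(self, reference_tables):
        fwd = panel_report_from_frequencies(reference_tables)
        rev = panel_report_from_frequencies(reference_tables[::-1])
        assert fwd.CPE == pytest.approx(rev.CPE, abs=1e-12)
        assert fwd.rows[0].cum_PE != rev.rows[0].cum_PE

    def test_cumulative_column_nondecreasing(self, reference_tables):
        rep = panel_report_from_frequencies(reference_tables)
        cums = [r.cum_PE for r in rep.rows]
        assert cums == sorted(cums)
        assert all(rep.CPE >= r.PE for r in rep.rows)

    def test_adaptive_cumulative_formatting(self, reference_tables):
        rep = panel_report_from_frequencies(reference_tables)
        assert format_cumulative(rep.CPE) == "0.999999472"
        assert format_cumulative(rep.rows[1].cum_PE) == "0.7226"
        assert format_cumulative(1.0 - 5e-15) == "0.999999999999995"
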