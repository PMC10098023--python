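"""Allele frequencies, the exact Fisher test, and reference contrasts."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import lipivar as lv
from lipivar.variant_io import MISSING


def brute_force_fisher(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: enumerate every 2x2 table with the observed
    margins and sum the exact probabilities of those no more likely than the
    observed table (exact rational arithmetic)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    obs_num = comb(r1, a) * comb(r2, c1 - a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= obs_num:
            total += Fraction(num, denom)
    return float(total)


class TestAlleleFrequency:
    def test_missing_excluded_from_both_terms(self):
        af = lv.allele_frequency([0, 1, 2, MISSING])
        assert (af.alt_count, af.called_alleles) == (3, 6)
        assert af.freq == pytest.approx(0.5)

    def test_high_frequency_site(self):
        """464 alt copies among 257 fully-called diploid samples."""
        codes = [2] * 207 + [1] * 50 + [0] * 0 + [MISSING]
        af = lv.allele_frequency(codes)
        assert af.alt_count == 464 and af.called_alleles == 514
        assert af.freq == pytest.approx(0.9027, abs=5e-5)

    def test_monomorphic(self):
        assert lv.allele_frequency([0, 0, 0]).freq == 0.0

    def test_all_missing_is_undefined_not_error(self):
        af = lv.allele_frequency([MISSING, MISSING])
        assert af.freq is None


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "freq, n, expected_alt",
        [
            (0.27976, 504, 282),
            (0.0, 100, 0),
            (1.0, 100, 200),
        ],
    )
    def test_examples(self, freq, n, expected_alt):
        alt, ref = lv.reconstruct_reference_counts(freq, n)
        assert alt == expected_alt
        assert alt + ref == 2 * n

    def test_round_trips_exact_rationals(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(50, 2505))
            alt = int(rng.integers(0, 2 * n + 1))
            freq = round(alt / (2 * n), 5)  # published precision
            assert lv.reconstruct_reference_counts(freq, n)[0] == alt


class TestInferAlleleCount:
    @pytest.mark.parametrize(
        "freq, expected",
        [
            (0.76163, (393, 516)),  # full cohort called
            (0.06615, (34, 514)),   # one sample missing at this site
            (0.9027, (464, 514)),
            (0.0719, (37, 514)),
        ],
    )
    def test_recovers_printed_count_and_denominator(self, freq, expected):
        assert lv.infer_allele_count(freq, 258) == expected


class TestFisherExact:
    def test_symmetric_table(self):
        assert lv.fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        expected = 2 * comb(10, 0) * comb(10, 10) / comb(20, 10)
        assert lv.fisher_exact_2x2(0, 10, 10, 0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            lv.fisher_exact_2x2(-1, 2, 3, 4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            lv.fisher_exact_2x2(0, 0, 0, 0)

    def test_degenerate_margin_gives_p_one(self):
        assert lv.fisher_exact_2x2(0, 10, 0, 20) == 1.0

    @given(st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert lv.fisher_exact_2x2(a, b, c, d) == pytest.approx(
            brute_force_fisher(a, b, c, d), abs=1e-12
        )

    @given(st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy(self, a, b, c, d):
        """Cross-check against the independent scipy implementation."""
        if a + b + c + d == 0:
            return
        expected = stats.fisher_exact([[a, b], [c, d]])[1]
        assert lv.fisher_exact_2x2(a, b, c, d) == pytest.approx(expected,
                                                               abs=1e-9)

    def test_large_table_path_agrees_with_scipy(self):
        # total > 500 takes the delegated path
        table = (40, 474, 180, 4828)
        assert lv.fisher_exact_2x2(*table) == pytest.approx(
            stats.fisher_exact([[40, 474], [180, 4828]])[1], rel=1e-9
        )


def _panel(freq_by_pop, n_by_pop):
    return lv.PopulationFreqPanel(
        {pop: (dict(freqs), n_by_pop[pop]) for pop, freqs in freq_by_pop.items()}
    )


class TestCompareToReference:
    def test_equal_frequencies_give_no_hits(self):
        cohort = [
            lv.AlleleFrequency(f"rs{i}", alt, 500)
            for i, alt in enumerate([10, 50, 250, 400])
        ]
        panel = _panel(
            {"ALL": {af.rsid: af.freq for af in cohort}}, {"ALL": 2504}
        )
        comparisons, counts = lv.compare_to_reference(cohort, panel)
        assert counts == {"ALL": 0}
        assert len(comparisons) == 4

    def test_single_variant_threshold_is_alpha(self):
        cohort = [lv.AlleleFrequency("rs1", 100, 500)]
        panel = _panel({"ALL": {"rs1": 0.2}}, {"ALL": 2504})
        (c,), _ = lv.compare_to_reference(cohort, panel, alpha=0.05)
        assert c.alpha_adjusted == pytest.approx(0.05)

    def test_absent_variants_skipped_per_population(self):
        cohort = [lv.AlleleFrequency("rs1", 10, 500),
                  lv.AlleleFrequency("rs2", 20, 500)]
        panel = _panel(
            {"ALL": {"rs1": 0.02, "rs2": 0.04}, "EAS": {"rs1": 0.02}},
            {"ALL": 2504, "EAS": 504},
        )
        comparisons, _ = lv.compare_to_reference(cohort, panel)
        eas = [c for c in comparisons if c.population == "EAS"]
        assert [c.rsid for c in eas] == ["rs1"]
        # per-population family: EAS tested m=1, ALL tested m=2
        assert eas[0].alpha_adjusted == pytest.approx(0.05)

    def test_empty_intersection_names_population(self):
        cohort = [lv.AlleleFrequency("rs1", 10, 500)]
        panel = _panel({"AMR": {"rsX": 0.5}}, {"AMR": 347})
        with pytest.raises(ValueError, match="AMR"):
            lv.compare_to_reference(cohort, panel)

    def test_significant_count_monotone_in_family_size(self):
        rng = np.random.default_rng(5)
        cohort = [
            lv.AlleleFrequency(f"rs{i}", int(rng.integers(0, 500)), 500)
            for i in range(60)
        ]
        panel = _panel(
            {"ALL": {af.rsid: min(1.0, max(0.0, af.freq + rng.normal(0, 0.05)))
                     for af in cohort}},
            {"ALL": 2504},
        )
        previous = None
        for m in (1, 10, 60, 600, 6000):
            _, counts = lv.compare_to_reference(cohort, panel, m=m)
            if previous is not None:
                assert counts["ALL"] <= previous
            previous = counts["ALL"]


class TestStarReproduction:
    def test_every_pharmaco_table_cell_reproduces(self):
        """Printed significance stars are re-derived from printed
        frequencies, 1KGP group sizes, and the Bonferroni family actually
        used (the number of variants tested)."""
        report = lv.reproduce_significance_flags(lv.load_paper_fixtures("table4"))
        assert len(report) == 44  # 9 variants x 5 populations, one no-data cell
        assert report["reproduced"].all()
        # and the smaller family alone already explains every cell
        assert (report["predicted_m2174"] == report["observed_star"]).all()

    @pytest.mark.parametrize("name, n_cells", [("table5", 39), ("table6", 29)])
    def test_other_result_tables_reproduce(self, name, n_cells):
        report = lv.reproduce_significance_flags(lv.load_paper_fixtures(name))
        assert len(report) == n_cells
        failures = report.loc[~report["reproduced"]]
        assert failures.empty, failures.to_string()
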