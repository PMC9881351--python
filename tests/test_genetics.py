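"""Allele statistics: counts, frequency-ratio CIs, chi-square and exact tests."""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import Table2x2

from neuromarker import (
    GenotypeTable,
    SynthConfig,
    allele_chi2,
    allele_counts,
    allele_ratio_ci,
    associate,
    dominant_test,
    gen_genotypes,
    odds_ratio_woolf,
)
from neuromarker.genetics import AlleleTable, percent


class TestAlleleCounts:
    def test_counts_and_percent_strings(self, table4_counts):
        at = allele_counts(table4_counts)
        assert (at.case_minor, at.case_major) == (15, 45)
        assert (at.control_minor, at.control_major) == (5, 55)
        pct = at.percent_strings
        assert pct["case"] == {"minor": "25.0", "major": "75.0"}
        assert pct["control"] == {"minor": "8.3", "major": "91.7"}

    def test_frequencies_sum_to_one(self, table4_counts):
        for group, f in allele_counts(table4_counts).frequencies.items():
            assert f["minor"] + f["major"] == pytest.approx(1.0)

    def test_percent_round_half_up(self):
        assert percent(1, 16) == "6.3"   # 6.25 rounds up
        assert percent(1, 8) == "12.5"

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            GenotypeTable("s", "G", "C", {"case": (1, -1, 2), "control": (0, 0, 3)})
        with pytest.raises(ValueError):
            GenotypeTable("s", "G", "C", {"case": (1, 1, 1)})


class TestFrequencyRatio:
    def test_katz_ci_on_printed_design(self, table4_counts):
        at = allele_counts(table4_counts)
        ratio, ci, degen = allele_ratio_ci(at)
        assert not degen
        assert round(ratio, 3) == 3.000
        assert round(ci[0], 3) == 1.164 and round(ci[1], 3) == 7.732
        major, mci, _ = allele_ratio_ci(at, allele="major")
        assert round(major, 3) == 0.818
        assert round(mci[0], 3) == 0.694 and round(mci[1], 3) == 0.965

    def test_matches_statsmodels_riskratio(self, table4_counts):
        """Independent oracle: Table2x2 risk-ratio CI on the allele table."""
        at = allele_counts(table4_counts)
        t22 = Table2x2(
            np.array([[at.case_minor, at.case_major],
                      [at.control_minor, at.control_major]])
        )
        ratio, ci, _ = allele_ratio_ci(at)
        assert ratio == pytest.approx(t22.riskratio)
        assert ci == pytest.approx(tuple(t22.riskratio_confint()), rel=1e-9)

    def test_minor_major_reciprocity(self, table4_counts):
        at = allele_counts(table4_counts)
        minor, _, _ = allele_ratio_ci(at)
        major, _, _ = allele_ratio_ci(at, allele="major")
        assert (minor > 1) == (major < 1)

    def test_equal_frequencies_ratio_one(self):
        at = AlleleTable("s", "G", "C", 10, 50, 10, 50)
        ratio, ci, _ = allele_ratio_ci(at)
        assert ratio == pytest.approx(1.0)
        assert ci[0] < 1 < ci[1]

    def test_label_swap_inverts_ratio(self, table4_counts):
        at = allele_counts(table4_counts)
        sw = AlleleTable("s", "G", "C", at.control_minor, at.control_major,
                         at.case_minor, at.case_major)
        r1, _, _ = allele_ratio_ci(at)
        r2, _, _ = allele_ratio_ci(sw)
        assert r1 == pytest.approx(1 / r2)
        assert allele_chi2(at)[1] == pytest.approx(allele_chi2(sw)[1])

    def test_degenerate_zero_counts_flagged(self):
        ratio, ci, degen = allele_ratio_ci(AlleleTable("s", "G", "C", 5, 55, 0, 60))
        assert degen and math.isinf(ratio) and ci is None
        ratio, ci, degen = allele_ratio_ci(AlleleTable("s", "G", "C", 0, 60, 5, 55))
        assert degen and ratio == 0.0

    def test_woolf_odds_ratio_distinct_from_frequency_ratio(self, table4_counts):
        at = allele_counts(table4_counts)
        orr, ci, _ = odds_ratio_woolf(at)
        assert orr == pytest.approx(15 * 55 / (45 * 5))  # 3.667, not 3.000
        assert ci[0] < orr < ci[1]


class TestChi2:
    def test_printed_design_chi2(self, table4_counts):
        chi2, p = allele_chi2(allele_counts(table4_counts))
        assert chi2 == pytest.approx(6.0)
        assert p == pytest.approx(stats.chi2.sf(6.0, 1))
        assert round(p, 3) == 0.014

    def test_flat_table_null(self):
        chi2, p = allele_chi2(AlleleTable("s", "G", "C", 10, 10, 10, 10))
        assert chi2 == 0.0 and p == 1.0

    def test_doubling_cells_doubles_chi2(self):
        a = AlleleTable("s", "G", "C", 15, 45, 5, 55)
        b = AlleleTable("s", "G", "C", 30, 90, 10, 110)
        assert allele_chi2(b)[0] == pytest.approx(2 * allele_chi2(a)[0])

    def test_zero_margin_error(self):
        with pytest.raises(ValueError, match="margin"):
            allele_chi2(AlleleTable("s", "G", "C", 0, 60, 0, 60))


def fisher_two_sided_oracle(table: np.ndarray) -> float:
    """Oracle: exhaustive enumeration over all tables with fixed margins,
    summing hypergeometric masses <= the observed table's mass."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        m = stats.hypergeom.pmf(x, n, col1, row1)
        if m <= obs * (1 + 1e-9):
            total += m
    return min(total, 1.0)


class TestDominant:
    def test_carrier_table_and_fisher(self, table4_counts):
        res = dominant_test(table4_counts)
        assert res["table"].tolist() == [[13, 17], [4, 26]]
        oracle = fisher_two_sided_oracle(res["table"])
        assert res["fisher_p"] == pytest.approx(oracle, rel=1e-9)
        assert res["fisher_p"] == pytest.approx(0.0204, abs=5e-4)

    def test_identical_fractions_p_one(self):
        t = GenotypeTable("s", "G", "C", {"case": (2, 8, 10), "control": (2, 8, 10)})
        assert dominant_test(t)["fisher_p"] == pytest.approx(1.0)

    def test_two_table_support_enumeration(self):
        t = GenotypeTable("s", "G", "C", {"case": (0, 1, 0), "control": (0, 0, 1)})
        assert dominant_test(t)["fisher_p"] == pytest.approx(1.0)

    def test_fisher_matches_enumeration_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            cells = rng.integers(0, 50, size=4)
            if cells[:2].sum() == 0 or cells[2:].sum() == 0:
                continue
            table = np.array(cells).reshape(2, 2)
            _, p = stats.fisher_exact(table)
            assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-6)


class TestGenerator:
    def test_from_subjects_round_trip(self):
        cfg = SynthConfig(seed=17)
        table, calls = gen_genotypes(cfg)
        rebuilt = GenotypeTable.from_subjects(calls, "snp_1", minor="G")
        assert rebuilt.counts == table.counts

    def test_null_ratio_near_one_over_seeds(self):
        ratios = []
        for seed in range(300):
            cfg = SynthConfig(seed=seed, rr_allele=1.0, control_maf=0.3)
            table, _ = gen_genotypes(cfg)
            r, _, degen = allele_ratio_ci(allele_counts(table))
            if not degen:
                ratios.append(np.log(r))
        assert np.mean(ratios) == pytest.approx(0.0, abs=0.05)

    def test_degenerate_world_flagged(self):
        cfg = SynthConfig(seed=1, rr_allele=0.0, control_maf=0.0)
        table, _ = gen_genotypes(cfg)
        res = associate(table)
        assert res.degenerate

    def test_associate_assembles_consistently(self, table4_counts):
        res = associate(table4_counts)
        assert res.ci95[0] <= res.allele_ratio <= res.ci95[1]
        assert res.dominant_p == res.dominant_tests["fisher_p"]
        assert res.percent_strings["case"]["minor"] == "25.0"
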