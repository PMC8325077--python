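"""Contingency tables, chi-square, Fisher exact and Welch t tests."""

import math
from math import comb

import numpy as np
import pytest

from surveyscreen import (
    ContingencyTable,
    build_contingency,
    chi_square_test,
    comparison_table,
    fisher_exact_2x2,
    format_p,
    run_pipeline,
    welch_t_test,
)
from surveyscreen.comparison import DegenerateTableError


def _table(rows):
    return ContingencyTable(
        row_labels=tuple(f"r{i}" for i in range(len(rows))),
        col_labels=tuple(f"c{j}" for j in range(len(rows[0]))),
        counts=tuple(tuple(r) for r in rows),
    )


def pearson_oracle(rows):
    """Textbook Pearson statistic, written independently of scipy."""
    n = sum(map(sum, rows))
    colsums = [sum(r[j] for r in rows) for j in range(len(rows[0]))]
    stat = 0.0
    for r in rows:
        rowsum = sum(r)
        for j, o in enumerate(r):
            e = rowsum * colsums[j] / n
            stat += (o - e) ** 2 / e
    return stat


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-9)
    )


class TestChiSquare:
    def test_no_association_gives_statistic_zero(self):
        res = chi_square_test(_table([[5, 5], [5, 5]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_textbook_formula_oracle(self):
        rows = [[93, 152], [388, 884], [60, 37], [28, 8]]
        res = chi_square_test(_table(rows))
        assert res.statistic == pytest.approx(pearson_oracle(rows), rel=1e-12)
        assert res.statistic == pytest.approx(72.26476357141703, rel=1e-9)
        assert res.df == 3
        assert res.p_value < 0.001

    def test_invariant_under_row_and_column_permutation(self):
        rows = [[12, 7], [3, 25], [9, 9]]
        base = chi_square_test(_table(rows))
        permuted = chi_square_test(_table([r[::-1] for r in rows[::-1]]))
        assert permuted.statistic == pytest.approx(base.statistic)
        assert permuted.p_value == pytest.approx(base.p_value)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(_table([[0, 0], [5, 5]]))


class TestFisherExact:
    def test_symmetric_table_gives_p_one(self):
        assert fisher_exact_2x2(_table([[1, 1], [1, 1]])).p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact_2x2(_table([[a, b], [c, d]])).p_value
            assert p == pytest.approx(
                fisher_enumeration_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(_table([[1, 1], [1, 1], [1, 1]]))

    def test_agrees_with_chi_square_on_large_balanced_tables(self):
        for rows in ([[500, 480], [450, 510]], [[1500, 1500], [1450, 1550]]):
            pf = fisher_exact_2x2(_table(rows)).p_value
            pc = chi_square_test(_table(rows)).p_value
            assert pf == pytest.approx(pc, rel=0.10)


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        res = welch_t_test([1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 5.5])
        assert res.statistic == pytest.approx(-1.2199885626608375, rel=1e-12)
        assert res.df == pytest.approx(3.9593147751605993, rel=1e-12)
        assert res.p_value == pytest.approx(0.29011471486717827, rel=1e-9)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_constant_equal_samples_p_one(self):
        res = welch_t_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0


class TestBuildContingency:
    def test_per_level_binary_matches_crosstab_oracle(self, small_cohort):
        records, _ = small_cohort
        decisions, _, _ = run_pipeline(records)
        tables = build_contingency(records, decisions, "cancer_care_status", "per_level_binary")
        by_id = {d.respondent_id: d for d in decisions}
        retained = [r for r in records if by_id[r.respondent_id].retained]
        excluded = [r for r in records if by_id[r.respondent_id].excluded]
        for level, table in tables.items():
            a = sum(level in r.cancer_care_status for r in retained)
            c = sum(level in r.cancer_care_status for r in excluded)
            assert table.counts == ((a, len(retained) - a), (c, len(excluded) - c))

    def test_single_select_drops_missing_and_empty_levels(self, small_cohort):
        records, _ = small_cohort
        decisions, _, _ = run_pipeline(records)
        table = build_contingency(records, decisions, "self_reported_health")
        n_answered = sum(r.self_reported_health is not None for r in records)
        assert int(np.sum(table.array)) <= n_answered
        assert all(sum(row) > 0 for row in table.counts)

    def test_unknown_variable_rejected(self, small_cohort):
        records, _ = small_cohort
        decisions, _, _ = run_pipeline(records)
        with pytest.raises(ValueError):
            build_contingency(records, decisions, "shoe_size")


class TestComparisonTable:
    def test_group_percentages_sum_to_100(self, small_cohort):
        records, _ = small_cohort
        decisions, _, _ = run_pipeline(records)
        table = build_contingency(records, decisions, "time_since_treatment")
        for col in (0, 1):
            total = sum(row[col] for row in table.counts)
            pct = sum(row[col] * 100 / total for row in table.counts)
            assert pct == pytest.approx(100.0)

    def test_runs_end_to_end_with_p_values(self, paper_cohort, paper_screen):
        records, _ = paper_cohort
        table = comparison_table(records, paper_screen.decisions_)
        assert len(table) > 30
        age_row = table[table["characteristic"].str.startswith("Current age")].iloc[0]
        assert age_row["p_value"] == "<.001"
        assert age_row["method"] == "welch_t"
        # legit records are older on average than planted fraud
        mean_ret = float(age_row["retained"].split(" ")[0])
        mean_exc = float(age_row["excluded"].split(" ")[0])
        assert mean_ret > mean_exc

    @pytest.mark.parametrize(
        "p, expected",
        [(0.0005, "<.001"), (0.045, ".045"), (0.06, ".06"), (0.5, ".50"),
         (0.92, ".92"), (0.008, ".008"), (1.0, "1.00")],
    )
    def test_p_value_formatting(self, p, expected):
        assert format_p(p) == expected
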