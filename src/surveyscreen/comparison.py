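"""Retained-vs-excluded comparison statistics.

Builds per-characteristic contingency tables over the two decision groups and
tests them with Pearson chi-square or, for sparse 2x2 tables, Fisher's exact
test; numeric characteristics are compared with Welch's unequal-variance t
test.  Output mirrors a standard epidemiology demographics table: n (%) per group,
mean (SD) for numeric items, and P values printed as "<.001" below 0.001.

Multi-select questions get one 2x2 table per level (selected vs not), each
with its own P value; single-select questions get one levels x 2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import EliminationDecision
from .schema import (
    MULTI_SELECT_FIELDS,
    SINGLE_SELECT_LEVELS,
    SurveyResponse,
)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "build_contingency",
    "chi_square_test",
    "fisher_exact_2x2",
    "welch_t_test",
    "comparison_table",
    "format_p",
    "DegenerateTableError",
]


class DegenerateTableError(ValueError):
    """A margin of the table is zero; no test is defined."""


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if arr.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table dimensions")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    method: str  # "chi_square" | "fisher_exact" | "welch_t"
    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def chi_square_test(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Pearson chi-square; continuity correction off by default."""
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row/column margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    return TestResult(method="chi_square", statistic=float(stat), p_value=float(p), df=float(df))


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test: sum of hypergeometric probabilities of all
    tables with the observed margins no more probable than the observed one."""
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(method="fisher_exact", statistic=float(odds), p_value=float(p))


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> TestResult:
    """Welch's t with Satterthwaite degrees of freedom, two-sided."""
    a = np.asarray([v for v in sample_a if v is not None and math.isfinite(v)], float)
    b = np.asarray([v for v in sample_b if v is not None and math.isfinite(v)], float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >=2 non-missing values")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        df = float(len(a) + len(b) - 2)  # identical constant samples
        return TestResult(method="welch_t", statistic=0.0, p_value=1.0, df=df)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return TestResult(
        method="welch_t", statistic=float(res.statistic), p_value=float(res.pvalue), df=float(df)
    )


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def _split_groups(
    cohort: Sequence[SurveyResponse], decisions: Sequence[EliminationDecision]
) -> tuple[list[SurveyResponse], list[SurveyResponse]]:
    by_id = {d.respondent_id: d for d in decisions}
    retained = [r for r in cohort if by_id[r.respondent_id].retained]
    excluded = [r for r in cohort if by_id[r.respondent_id].excluded]
    return retained, excluded


def build_contingency(
    cohort: Sequence[SurveyResponse],
    decisions: Sequence[EliminationDecision],
    variable: str,
    mode: str = "single_select",
    levels: Sequence[str] | None = None,
) -> ContingencyTable | dict[str, ContingencyTable]:
    """Contingency table(s) of *variable* against retained/excluded status.

    ``single_select`` -> one levels x 2 table (columns retained, excluded;
    missing answers dropped).  ``per_level_binary`` -> a dict of one 2x2 table
    per level, rows (retained, excluded) x columns (selected, not selected);
    the "not selected" cell uses the full group size, matching per-level
    P values for multi-select questions.
    """
    retained, excluded = _split_groups(cohort, decisions)

    if mode == "single_select":
        if variable in SINGLE_SELECT_LEVELS:
            lv = tuple(levels) if levels is not None else SINGLE_SELECT_LEVELS[variable]
            getter = lambda r: getattr(r, variable)  # noqa: E731
        elif variable == "tribe_or_territory":
            lv = ("yes", "no")
            getter = lambda r: (  # noqa: E731
                None if r.tribe_or_territory is None else ("yes" if r.tribe_or_territory else "no")
            )
        else:
            raise ValueError(f"unknown single-select variable {variable!r}")
        counts = tuple(
            (
                sum(getter(r) == level for r in retained),
                sum(getter(r) == level for r in excluded),
            )
            for level in lv
        )
        # drop all-empty levels so margins stay meaningful
        keep = [i for i, row in enumerate(counts) if sum(row) > 0]
        if len(keep) < 2:
            raise DegenerateTableError(f"variable {variable!r} has <2 observed levels")
        return ContingencyTable(
            row_labels=tuple(lv[i] for i in keep),
            col_labels=("retained", "excluded"),
            counts=tuple(counts[i] for i in keep),
        )

    if mode == "per_level_binary":
        if variable not in MULTI_SELECT_FIELDS:
            raise ValueError(f"unknown multi-select variable {variable!r}")
        _, lv_all = MULTI_SELECT_FIELDS[variable]
        lv = tuple(levels) if levels is not None else lv_all
        tables: dict[str, ContingencyTable] = {}
        for level in lv:
            a = sum(level in getattr(r, variable) for r in retained)
            c = sum(level in getattr(r, variable) for r in excluded)
            tables[level] = ContingencyTable(
                row_labels=("retained", "excluded"),
                col_labels=("selected", "not_selected"),
                counts=((a, len(retained) - a), (c, len(excluded) - c)),
            )
        return tables

    raise ValueError(f"unknown mode {mode!r}")


def _auto_test(table: ContingencyTable, yates: bool = False) -> TestResult:
    """Chi-square with Fisher fallback when any expected count < 5 (2x2 only)."""
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero margin")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if arr.shape == (2, 2) and (expected < 5).any():
        return fisher_exact_2x2(table)
    return chi_square_test(table, yates=yates)


def format_p(p: float) -> str:
    """JAMA-style: "<.001" below 0.001, otherwise 3 decimals trimmed to at
    least 2 (0.500 -> ".50", 0.045 -> ".045")."""
    if p < 0.001:
        return "<.001"
    s = f"{p:.3f}"
    if s.endswith("0"):
        s = s[:-1]
    return s[1:] if s.startswith("0") else s


#: Default variable plan: (display name, field, kind)
DEFAULT_COMPARISON_VARIABLES: tuple[tuple[str, str, str], ...] = (
    ("Current age (years)", "reported_age", "numeric"),
    ("Gender", "gender_identities", "multi_select"),
    ("Sexual orientation", "sexual_orientation", "single_select"),
    ("Race/ethnicity", "race_ethnicities", "multi_select"),
    ("Partnership status", "marital_status", "single_select"),
    ("Number of individuals in household", "household_size", "numeric"),
    ("Education", "education", "single_select"),
    ("Annual household income", "income_bracket", "single_select"),
    ("Age at cancer diagnosis (years)", "age_at_diagnosis", "numeric"),
    ("Cancer stage", "cancer_stage", "single_select"),
    ("Cancer type", "cancer_types", "multi_select"),
    ("Time since cancer treatment (years)", "time_since_treatment", "single_select"),
    ("Cancer care status", "cancer_care_status", "multi_select"),
    ("Part of a tribe or territory", "tribe_or_territory", "binary"),
    ("Employment status", "employment_status", "multi_select"),
    ("Insurance type", "insurance_types", "multi_select"),
    ("Self-reported health", "self_reported_health", "single_select"),
)


def comparison_table(
    cohort: Sequence[SurveyResponse],
    decisions: Sequence[EliminationDecision],
    variables: Sequence[tuple[str, str, str]] = DEFAULT_COMPARISON_VARIABLES,
) -> pd.DataFrame:
    """Demographics comparison of retained vs excluded respondents.

    One row per characteristic (numeric: mean (SD) per group, Welch t) or per
    level (categorical: n (%) per group; single-select levels share one
    variable-wide chi-square P, multi-select levels each get their own
    chi-square/Fisher P).  Percentage denominators are the group sizes.
    """
    retained, excluded = _split_groups(cohort, decisions)
    n_ret, n_exc = len(retained), len(excluded)
    rows: list[dict] = []

    def pct_cell(n: int, denom: int) -> str:
        return f"{n} ({n * 100 / denom:.1f})" if denom else f"{n} (-)"

    for display, field, kind in variables:
        if kind == "numeric":
            a = [getattr(r, field) for r in retained if getattr(r, field) is not None]
            b = [getattr(r, field) for r in excluded if getattr(r, field) is not None]
            try:
                res = welch_t_test(a, b)
                p_str = format_p(res.p_value)
            except ValueError:
                res, p_str = None, ""
            rows.append(
                {
                    "characteristic": f"{display}, mean (SD)",
                    "level": "",
                    "retained": f"{np.mean(a):.1f} ({np.std(a, ddof=1):.1f})" if len(a) > 1 else "",
                    "excluded": f"{np.mean(b):.1f} ({np.std(b, ddof=1):.1f})" if len(b) > 1 else "",
                    "p_value": p_str,
                    "method": res.method if res else "",
                }
            )
        elif kind in ("single_select", "binary"):
            variable = field
            try:
                table = build_contingency(cohort, decisions, variable, "single_select")
                res = _auto_test(table)
                p_str = format_p(res.p_value)
                method = res.method
            except DegenerateTableError:
                table, p_str, method = None, "", ""
            rows.append(
                {"characteristic": f"{display}, n (%)", "level": "", "retained": "",
                 "excluded": "", "p_value": p_str, "method": method}
            )
            if table is not None:
                for i, level in enumerate(table.row_labels):
                    rows.append(
                        {
                            "characteristic": "",
                            "level": level,
                            "retained": pct_cell(table.counts[i][0], n_ret),
                            "excluded": pct_cell(table.counts[i][1], n_exc),
                            "p_value": "",
                            "method": "",
                        }
                    )
        elif kind == "multi_select":
            tables = build_contingency(cohort, decisions, field, "per_level_binary")
            rows.append(
                {"characteristic": f"{display}, n (%)", "level": "", "retained": "",
                 "excluded": "", "p_value": "", "method": ""}
            )
            for level, table in tables.items():
                a, c = table.counts[0][0], table.counts[1][0]
                if a + c == 0:
                    continue
                try:
                    res = _auto_test(table)
                    p_str, method = format_p(res.p_value), res.method
                except DegenerateTableError:
                    p_str, method = "", ""
                rows.append(
                    {
                        "characteristic": "",
                        "level": level,
                        "retained": pct_cell(a, n_ret),
                        "excluded": pct_cell(c, n_exc),
                        "p_value": p_str,
                        "method": method,
                    }
                )
        else:
            raise ValueError(f"unknown variable kind {kind!r}")
    return pd.DataFrame(rows)


def comparison_markdown(table: pd.DataFrame) -> str:
    """Render the comparison DataFrame as a Markdown table."""
    lines = ["| Characteristic | Retained | Excluded | P value |", "| --- | --- | --- | --- |"]
    for _, row in table.iterrows():
        name = row["characteristic"] or f"&nbsp;&nbsp;{row['level']}"
        lines.append(f"| {name} | {row['retained']} | {row['excluded']} | {row['p_value']} |")
    return "\n".join(lines) + "\n"
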