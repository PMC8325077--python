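"""Read and write respondent cohorts as REDCap-style wide CSV.

Layout conventions
------------------
* one row per respondent, RFC-4180 quoting;
* multi-select questions are exported checkbox-style, one 0/1 column per
  level, named ``<prefix>___<level>`` (e.g. ``gender___cisgender_female``);
* timestamps are ISO-8601; naive values are interpreted as US Eastern when
  the config says so (the default), otherwise rejected as unparseable;
* an empty cell is a missing answer.  Cells that fail to parse (bad date,
  non-integer age, unknown categorical level) also become missing — fraud
  screening must tolerate garbage input, that is its job.
"""

from __future__ import annotations

import csv
from datetime import date, datetime
from pathlib import Path

from .schema import (
    EASTERN,
    MULTI_SELECT_FIELDS,
    SINGLE_SELECT_LEVELS,
    QuestionInventory,
    SurveyResponse,
)

__all__ = ["read_responses", "write_responses", "SchemaError", "IntegrityError"]


class SchemaError(ValueError):
    """The file's columns do not match the expected schema."""


class IntegrityError(ValueError):
    """The file violates a cohort invariant (e.g. duplicate respondent ids)."""


_SCALAR_COLUMNS: tuple[str, ...] = (
    "respondent_id",
    "submission_timestamp",
    "survey_source",
    "survey_source_detail",
    "reported_age",
    "date_of_birth",
    "sex_assigned_at_birth",
    "sexual_orientation",
    "marital_status",
    "household_size",
    "education",
    "income_bracket",
    "country_of_residence",
    "cancer_stage",
    "age_at_diagnosis",
    "time_since_diagnosis",
    "time_since_treatment",
    "tribe_or_territory",
    "self_reported_health",
    "telehealth_comment",
    "final_suggestion",
    "email",
    "first_name",
    "last_name",
    "name_suffix",
    "postal_address",
    "honeypot_value",
    "retyped_word",
    "acknowledgement_checked",
)

_INT_FIELDS = {"reported_age", "household_size", "age_at_diagnosis"}
_BOOL_FIELDS = {"tribe_or_territory", "acknowledgement_checked"}
_TEXT_FIELDS = {
    "survey_source_detail",
    "telehealth_comment",
    "final_suggestion",
    "email",
    "first_name",
    "last_name",
    "name_suffix",
    "postal_address",
    "honeypot_value",
    "retyped_word",
}


def expected_columns() -> list[str]:
    cols = list(_SCALAR_COLUMNS)
    for prefix, levels in MULTI_SELECT_FIELDS.values():
        cols.extend(f"{prefix}___{level}" for level in levels)
    return cols


def _parse_timestamp(cell: str, naive_is_eastern: bool) -> datetime | None:
    try:
        ts = datetime.fromisoformat(cell)
    except ValueError:
        return None
    if ts.tzinfo is None:
        if not naive_is_eastern:
            return None
        ts = ts.replace(tzinfo=EASTERN)
    return ts


def _parse_scalar(field: str, cell: str, naive_is_eastern: bool):
    cell = cell.strip()
    if cell == "":
        return "" if field in _TEXT_FIELDS else None
    if field in _TEXT_FIELDS:
        return cell
    if field == "submission_timestamp":
        return _parse_timestamp(cell, naive_is_eastern)
    if field == "date_of_birth":
        try:
            return date.fromisoformat(cell)
        except ValueError:
            return None
    if field in _INT_FIELDS:
        try:
            return int(cell)
        except ValueError:
            return None
    if field in _BOOL_FIELDS:
        return {"1": True, "0": False, "true": True, "false": False}.get(cell.lower())
    if field in SINGLE_SELECT_LEVELS:
        return cell if cell in SINGLE_SELECT_LEVELS[field] else None
    if field == "country_of_residence":
        return cell
    return cell


def read_responses(
    path: str | Path,
    inventory: QuestionInventory | None = None,
    naive_timestamps_eastern: bool = True,
) -> list[SurveyResponse]:
    """Parse a cohort CSV into :class:`SurveyResponse` records.

    Raises :class:`SchemaError` if mandatory columns are absent (the error
    names them) and :class:`IntegrityError` on duplicate respondent ids.
    Unparseable cells become missing answers rather than hard errors.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in expected_columns() if c not in header]
        if missing_cols:
            raise SchemaError(f"missing mandatory columns: {missing_cols}")
        records: list[SurveyResponse] = []
        seen: set[str] = set()
        for row in reader:
            rid = (row.get("respondent_id") or "").strip()
            if rid in seen:
                raise IntegrityError(f"duplicate respondent_id: {rid!r}")
            seen.add(rid)
            kwargs = {
                f: _parse_scalar(f, row.get(f, ""), naive_timestamps_eastern)
                for f in _SCALAR_COLUMNS
                if f != "respondent_id"
            }
            for field, (prefix, levels) in MULTI_SELECT_FIELDS.items():
                kwargs[field] = {
                    level
                    for level in levels
                    if (row.get(f"{prefix}___{level}", "") or "").strip() == "1"
                }
            records.append(SurveyResponse(respondent_id=rid, **kwargs))
    return records


def _format_scalar(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, date):
        return value.isoformat()
    return str(value)


def write_responses(records: list[SurveyResponse], path: str | Path) -> None:
    """Write a cohort CSV such that ``read_responses`` round-trips it exactly."""
    path = Path(path)
    cols = expected_columns()
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for rec in records:
            row = {f: _format_scalar(getattr(rec, f)) for f in _SCALAR_COLUMNS}
            for field, (prefix, levels) in MULTI_SELECT_FIELDS.items():
                selected = getattr(rec, field)
                for level in levels:
                    row[f"{prefix}___{level}"] = "1" if level in selected else "0"
            writer.writerow(row)
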