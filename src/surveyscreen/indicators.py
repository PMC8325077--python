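"""The twelve suspicious-response indicators.

Each detector answers one question about a record (or, for the duplicate and
timing detectors, about the whole cohort):

====================== ======================================================
AGE_DISCORD            year of birth equals the submission year, or reported
                       age and DOB-calculated age differ by more than 1 year
RARE_CANCER_YOUNG      reported age < 40 with a cancer type rare before 40
SOURCE_INCONGRUENT     claimed survey source predates that source's
                       dissemination date
OFFTOPIC_TEXT          open-text answers are IT jargon, not about care
DUP_TELEHEALTH         telehealth comment duplicated across respondents
DUP_SUGGESTION         final open-ended suggestion duplicated
DUP_EMAIL              email address duplicated
TIMELINE_DX_LT2_TX_2TO5  diagnosed <2 years ago but treated 2-5 years ago
TIMELINE_DX_LE5_TX_GT5   diagnosed <=5 years ago but treated >5 years ago
SUSPICIOUS_TIMING      member of a run of >=10 submissions each within 5
                       minutes of the next, or submitted 00:00-04:00 Eastern
SUSPICIOUS_EMAIL_ADDRESS  random-looking email local part, strange
                       punctuation/capitalisation, or a structurally bogus
                       postal address
SUSPICIOUS_NAME        flipped first/last name, name-part crossover, suffix
                       inconsistent with the given name, or junk suffix
====================== ======================================================

Record-local detectors are pure functions of one record plus configuration;
the duplicate and timing detectors see the cohort but are order-invariant.
A non-empty honeypot value is available as an optional thirteenth indicator
(disabled by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from sklearn.base import BaseEstimator

from .config import (
    DisseminationCalendar,
    Lexicons,
    RareCancerCatalog,
    ScreeningThresholds,
)
from .schema import SurveyResponse, floor_age

__all__ = [
    "INDICATOR_CODES",
    "HONEYPOT_CODE",
    "IndicatorProfile",
    "IndicatorProfiler",
    "profile_cohort",
    "flag_age_discordance",
    "flag_rare_cancer_young",
    "flag_source_incongruence",
    "flag_offtopic_text",
    "flag_duplicate_text",
    "flag_duplicate_email",
    "flag_timeline_inconsistency",
    "flag_suspicious_timing",
    "flag_suspicious_email_address",
    "flag_suspicious_name",
]

INDICATOR_CODES: tuple[str, ...] = (
    "AGE_DISCORD",
    "RARE_CANCER_YOUNG",
    "SOURCE_INCONGRUENT",
    "OFFTOPIC_TEXT",
    "DUP_TELEHEALTH",
    "DUP_SUGGESTION",
    "DUP_EMAIL",
    "TIMELINE_DX_LT2_TX_2TO5",
    "TIMELINE_DX_LE5_TX_GT5",
    "SUSPICIOUS_TIMING",
    "SUSPICIOUS_EMAIL_ADDRESS",
    "SUSPICIOUS_NAME",
)

HONEYPOT_CODE = "HONEYPOT"


@dataclass(frozen=True)
class IndicatorProfile:
    respondent_id: str
    fired: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.fired)


# ---------------------------------------------------------------------------
# Record-local detectors
# ---------------------------------------------------------------------------

def flag_age_discordance(
    record: SurveyResponse, thresholds: ScreeningThresholds | None = None
) -> bool:
    t = thresholds or ScreeningThresholds()
    submitted = record.submitted_eastern()
    if submitted is None or record.date_of_birth is None:
        return False
    if record.date_of_birth.year == submitted.year:
        return True  # degenerate "born this year" DOB
    if record.reported_age is None:
        return False
    calculated = floor_age(record.date_of_birth, submitted.date())
    return abs(record.reported_age - calculated) > t.age_discordance_years


def flag_rare_cancer_young(
    record: SurveyResponse,
    catalog: RareCancerCatalog | None = None,
    thresholds: ScreeningThresholds | None = None,
) -> bool:
    t = thresholds or ScreeningThresholds()
    cat = catalog or RareCancerCatalog()
    if record.reported_age is None or record.reported_age >= t.young_age_cutoff:
        return False
    return bool(record.cancer_types & cat.types)


def flag_source_incongruence(
    record: SurveyResponse, calendar: DisseminationCalendar | None = None
) -> bool:
    cal = calendar or DisseminationCalendar()
    submitted = record.submitted_eastern()
    if submitted is None:
        return False
    earliest = cal.earliest_date(record.survey_source)
    if earliest is None:
        return False
    return submitted.date() < earliest


def _normalize_text(text: str) -> str:
    text = text.lower()
    text = re.sub(r"[^\w\s]", " ", text)
    return re.sub(r"\s+", " ", text).strip()


def _lexicon_hits(normalized: str, lexicon: Sequence[str]) -> int:
    padded = f" {normalized} "
    return sum(1 for term in lexicon if f" {term} " in padded)


def flag_offtopic_text(
    record: SurveyResponse, lexicons: Lexicons | None = None
) -> bool:
    """IT-jargon open text with no care-related term anywhere in the record's
    open-text answers."""
    lex = lexicons or Lexicons.bundled()
    for text in (record.telehealth_comment, record.final_suggestion):
        norm = _normalize_text(text)
        if not norm:
            continue
        if _lexicon_hits(norm, lex.it_terms) >= 1 and _lexicon_hits(norm, lex.on_topic_terms) == 0:
            return True
    return False


def flag_timeline_inconsistency(record: SurveyResponse) -> frozenset[str]:
    dx, tx = record.time_since_diagnosis, record.time_since_treatment
    if dx is None or tx is None:
        return frozenset()
    fired = set()
    if dx == "<2" and tx == "2-5":
        fired.add("TIMELINE_DX_LT2_TX_2TO5")
    if dx in ("<2", "2-5") and tx == ">5":
        fired.add("TIMELINE_DX_LE5_TX_GT5")
    return frozenset(fired)


# -- identity heuristics -----------------------------------------------------

_ALNUM_RUN_RE = re.compile(r"[A-Za-z0-9]+")
_VOWELS = set("aeiouyAEIOUY")
#: "strange punctuation or capitalisation" in an email address
_EMAIL_ANOMALY_RES = (
    re.compile(r"\.\."),                      # consecutive dots
    re.compile(r"(?:[a-z][A-Z]){3,}"),        # aLtErNaTiNg case
    re.compile(r"[\"'!#$%^&*(),;<>]"),        # quoting / shouting punctuation
)
_ADDRESS_ALTCAP_RE = re.compile(r"\b\w*[a-z][A-Z]\w*")
_ADDRESS_MULTISPACE_RE = re.compile(r"\S\s{2,}\S")


def _run_is_random(run: str, min_length: int) -> bool:
    if len(run) < min_length:
        return False
    has_digit = any(c.isdigit() for c in run)
    has_alpha = any(c.isalpha() for c in run)
    if has_digit and has_alpha:
        return True
    # all-letter runs: random iff some 5-char window has no vowel
    if has_alpha and not has_digit:
        return any(
            not (_VOWELS & set(run[i : i + 5])) for i in range(len(run) - 4)
        )
    return has_digit  # long pure-digit run


def flag_suspicious_email_address(
    record: SurveyResponse,
    thresholds: ScreeningThresholds | None = None,
    lexicons: Lexicons | None = None,
) -> bool:
    t = thresholds or ScreeningThresholds()
    lex = lexicons or Lexicons.bundled()

    email = record.email.strip()
    if email:
        local = email.split("@", 1)[0]
        for run in _ALNUM_RUN_RE.findall(local):
            if _run_is_random(run, t.random_run_min_length):
                return True
        if any(rx.search(email) for rx in _EMAIL_ANOMALY_RES):
            return True

    address = record.postal_address.strip()
    if address:
        if '"' in address:
            return True
        if len(address.split()) < t.address_min_tokens:
            return True  # incomplete address
        norm = _normalize_text(address)
        if _lexicon_hits(norm, lex.business_terms) >= 1:
            return True
        if _ADDRESS_ALTCAP_RE.search(address) or _ADDRESS_MULTISPACE_RE.search(address):
            return True
    return False


def flag_suspicious_name(
    record: SurveyResponse,
    lexicons: Lexicons | None = None,
    thresholds: ScreeningThresholds | None = None,
) -> bool:
    lex = lexicons or Lexicons.bundled()
    lex.require_name_lists()
    givens = lex.given_names
    surnames = frozenset(lex.surnames)

    first = record.first_name.strip().lower()
    last = record.last_name.strip().lower()
    suffix = record.name_suffix.strip().lower().rstrip(".")

    # flipped first/last per the bundled frequency lists
    if first and last:
        if first in surnames and first not in givens and last in givens and last not in surnames:
            return True
        # part of one name field inside the other (crossover), min 3 chars
        if len(first) >= 3 and len(last) >= 3 and first != last:
            if first in last or last in first:
                return True

    if suffix:
        if any(c.isdigit() for c in suffix):
            return True
        if suffix not in lex.suffix_whitelist:
            return True
        # generational (male-line) suffix on a list-marked female given name
        if suffix in lex.male_suffixes:
            if first in set(lex.given_names_female) and first not in set(lex.given_names_male):
                return True
    return False


def flag_honeypot(record: SurveyResponse) -> bool:
    """Optional thirteenth indicator: hidden item answered (bot behaviour)."""
    return bool(record.honeypot_value.strip())


# ---------------------------------------------------------------------------
# Cohort-level detectors
# ---------------------------------------------------------------------------

def flag_duplicate_text(
    cohort: Sequence[SurveyResponse],
    field: str,
    min_length: int | None = None,
) -> set[str]:
    """Respondent ids whose normalized text in *field* is shared by >=2
    records.  Texts shorter than *min_length* (default 15 chars after
    normalization) never flag — "none"/"n/a" style answers are not evidence.
    """
    if field not in ("telehealth_comment", "final_suggestion"):
        raise ValueError(f"unsupported duplicate-text field: {field!r}")
    min_len = ScreeningThresholds().duplicate_text_min_length if min_length is None else min_length
    groups: dict[str, list[str]] = {}
    for rec in cohort:
        norm = _normalize_text(getattr(rec, field))
        if len(norm) >= min_len:
            groups.setdefault(norm, []).append(rec.respondent_id)
    return {rid for ids in groups.values() if len(ids) >= 2 for rid in ids}


def flag_duplicate_email(cohort: Sequence[SurveyResponse]) -> set[str]:
    groups: dict[str, list[str]] = {}
    for rec in cohort:
        norm = rec.email.strip().lower()
        if norm:
            groups.setdefault(norm, []).append(rec.respondent_id)
    return {rid for ids in groups.values() if len(ids) >= 2 for rid in ids}


def flag_suspicious_timing(
    cohort: Sequence[SurveyResponse],
    thresholds: ScreeningThresholds | None = None,
) -> set[str]:
    """Burst members plus night-window submissions.

    Bursts are maximal runs, in timestamp order, in which every successive
    gap is at most ``burst_max_gap``; every member of a run of length
    >= ``burst_min_run`` is flagged.  Independently, any record whose Eastern
    local time falls in [night_window_start, night_window_end) is flagged.
    """
    t = thresholds or ScreeningThresholds()
    flagged: set[str] = set()

    stamped = [
        (rec.submitted_eastern(), rec.respondent_id)
        for rec in cohort
        if rec.submission_timestamp is not None
    ]
    stamped.sort(key=lambda pair: (pair[0], pair[1]))

    run: list[str] = []
    prev = None
    for ts, rid in stamped:
        if prev is not None and ts - prev <= t.burst_max_gap:
            run.append(rid)
        else:
            if len(run) >= t.burst_min_run:
                flagged.update(run)
            run = [rid]
        prev = ts
    if len(run) >= t.burst_min_run:
        flagged.update(run)

    for ts, rid in stamped:
        if t.night_window_start <= ts.time() < t.night_window_end:
            flagged.add(rid)
    return flagged


# ---------------------------------------------------------------------------
# Profiler
# ---------------------------------------------------------------------------

class IndicatorProfiler(BaseEstimator):
    """Runs all detectors over a cohort and unions per-record fired sets.

    ``fit(X)`` computes :attr:`profiles_` (one :class:`IndicatorProfile` per
    record, same order as X) and :attr:`marginal_counts_` (records fired per
    indicator).  Individuals count in as many indicators as their responses
    suggest, so marginal counts need not sum to any elimination total.
    """

    def __init__(
        self,
        thresholds: ScreeningThresholds | None = None,
        calendar: DisseminationCalendar | None = None,
        catalog: RareCancerCatalog | None = None,
        lexicons: Lexicons | None = None,
        enable_honeypot: bool = False,
    ):
        self.thresholds = thresholds
        self.calendar = calendar
        self.catalog = catalog
        self.lexicons = lexicons
        self.enable_honeypot = enable_honeypot

    def fit(self, X: Sequence[SurveyResponse], y=None) -> "IndicatorProfiler":
        t = self.thresholds or ScreeningThresholds()
        cal = self.calendar or DisseminationCalendar()
        cat = self.catalog or RareCancerCatalog()
        lex = self.lexicons or Lexicons.bundled()
        lex.require_name_lists()
        cal.validate_sources(
            {r.survey_source for r in X if r.survey_source is not None}
        )

        dup_tele = flag_duplicate_text(X, "telehealth_comment", t.duplicate_text_min_length)
        dup_sugg = flag_duplicate_text(X, "final_suggestion", t.duplicate_text_min_length)
        dup_email = flag_duplicate_email(X)
        timing = flag_suspicious_timing(X, t)

        profiles: list[IndicatorProfile] = []
        for rec in X:
            fired: set[str] = set(flag_timeline_inconsistency(rec))
            if flag_age_discordance(rec, t):
                fired.add("AGE_DISCORD")
            if flag_rare_cancer_young(rec, cat, t):
                fired.add("RARE_CANCER_YOUNG")
            if flag_source_incongruence(rec, cal):
                fired.add("SOURCE_INCONGRUENT")
            if flag_offtopic_text(rec, lex):
                fired.add("OFFTOPIC_TEXT")
            if rec.respondent_id in dup_tele:
                fired.add("DUP_TELEHEALTH")
            if rec.respondent_id in dup_sugg:
                fired.add("DUP_SUGGESTION")
            if rec.respondent_id in dup_email:
                fired.add("DUP_EMAIL")
            if rec.respondent_id in timing:
                fired.add("SUSPICIOUS_TIMING")
            if flag_suspicious_email_address(rec, t, lex):
                fired.add("SUSPICIOUS_EMAIL_ADDRESS")
            if flag_suspicious_name(rec, lex, t):
                fired.add("SUSPICIOUS_NAME")
            if self.enable_honeypot and flag_honeypot(rec):
                fired.add(HONEYPOT_CODE)
            profiles.append(IndicatorProfile(rec.respondent_id, frozenset(fired)))

        codes = INDICATOR_CODES + ((HONEYPOT_CODE,) if self.enable_honeypot else ())
        self.profiles_ = profiles
        self.marginal_counts_ = {
            code: sum(code in p.fired for p in profiles) for code in codes
        }
        return self

    def fit_predict(self, X: Sequence[SurveyResponse], y=None) -> list[int]:
        """Per-record indicator counts."""
        self.fit(X)
        return [p.count for p in self.profiles_]


def profile_cohort(
    cohort: Sequence[SurveyResponse],
    calendar: DisseminationCalendar | None = None,
    catalog: RareCancerCatalog | None = None,
    thresholds: ScreeningThresholds | None = None,
    lexicons: Lexicons | None = None,
    enable_honeypot: bool = False,
) -> list[IndicatorProfile]:
    """Functional wrapper over :class:`IndicatorProfiler`."""
    profiler = IndicatorProfiler(
        thresholds=thresholds,
        calendar=calendar,
        catalog=catalog,
        lexicons=lexicons,
        enable_honeypot=enable_honeypot,
    ).fit(cohort)
    return profiler.profiles_
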