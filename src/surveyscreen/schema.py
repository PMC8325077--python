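"""Survey-response data model.

One :class:`SurveyResponse` holds everything a screening rule can touch for a
single respondent: demographics, cancer history, open-text answers, identity
fields, the submission timestamp and the bot-trap fields (honeypot, retyped
word, acknowledgement checkbox).

All timestamps are timezone-aware; rule comparisons happen in US Eastern time
(the cohort's canonical timezone), so :func:`to_eastern` is used everywhere a
clock-time or calendar-date comparison is made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime
from zoneinfo import ZoneInfo

EASTERN = ZoneInfo("America/New_York")

# ---------------------------------------------------------------------------
# Categorical level sets
# ---------------------------------------------------------------------------

GENDER_LEVELS = (
    "cisgender_male",
    "cisgender_female",
    "transgender_male",
    "transgender_female",
    "gender_fluid",
    "two_spirit",
    "other",
    "prefer_not_to_answer",
    "do_not_understand",
)

SEX_LEVELS = ("male", "female", "prefer_not_to_answer")

ORIENTATION_LEVELS = (
    "straight",
    "lgbq_two_spirit",
    "other_prefer_not_do_not_understand",
)

RACE_LEVELS = (
    "asian",
    "black",
    "hispanic_latinx",
    "native_american_alaska_native_pacific_islander",
    "white",
    "other",
    "prefer_not_to_answer",
)

MARITAL_LEVELS = ("single", "married_partnered", "divorced_separated", "widowed")

EDUCATION_LEVELS = (
    "some_high_school_or_less",
    "high_school_ged_vocational",
    "some_college",
    "completed_4_year_degree",
    "graduate_school",
)

INCOME_LEVELS = (
    "lt_25000",
    "25001_50000",
    "50001_75000",
    "75001_100000",
    "gt_100000",
    "prefer_not_to_answer",
)

STAGE_LEVELS = ("0", "I", "II", "III", "IV", "unknown", "none")

CANCER_TYPE_LEVELS = (
    "melanoma",
    "lung",
    "prostate",
    "breast",
    "colorectal",
    "kidney",
    "bladder",
    "blood",
    "uterine_cervical",
    "thyroid",
    "nonmelanoma_skin",
    "other",
)

TIME_CATEGORY_LEVELS = ("<2", "2-5", ">5")

CARE_STATUS_LEVELS = (
    "remission_or_ned",
    "chronic",
    "palliative",
    "hospice",
    "none_apply",
)

EMPLOYMENT_LEVELS = ("retired", "paid_work", "unpaid_work", "unemployed")

INSURANCE_LEVELS = (
    "private",
    "medicaid",
    "medicare",
    "tricare_cobra_other",
    "uninsured",
)

HEALTH_LEVELS = ("excellent_very_good", "good", "fair", "poor")

SOURCE_LEVELS = (
    "coc_email",
    "community_partner",
    "accc_exchange",
    "aosw_listserv",
    "gwu_newsletter",
    "social_media",
    "other",
)

# field name -> allowed levels, for validation on read
SINGLE_SELECT_LEVELS: dict[str, tuple[str, ...]] = {
    "survey_source": SOURCE_LEVELS,
    "sex_assigned_at_birth": SEX_LEVELS,
    "sexual_orientation": ORIENTATION_LEVELS,
    "marital_status": MARITAL_LEVELS,
    "education": EDUCATION_LEVELS,
    "income_bracket": INCOME_LEVELS,
    "cancer_stage": STAGE_LEVELS,
    "time_since_diagnosis": TIME_CATEGORY_LEVELS,
    "time_since_treatment": TIME_CATEGORY_LEVELS,
    "self_reported_health": HEALTH_LEVELS,
}

# field name -> (CSV column prefix, allowed levels)
MULTI_SELECT_FIELDS: dict[str, tuple[str, tuple[str, ...]]] = {
    "gender_identities": ("gender", GENDER_LEVELS),
    "race_ethnicities": ("race", RACE_LEVELS),
    "cancer_types": ("cancer_type", CANCER_TYPE_LEVELS),
    "cancer_care_status": ("care_status", CARE_STATUS_LEVELS),
    "employment_status": ("employment", EMPLOYMENT_LEVELS),
    "insurance_types": ("insurance", INSURANCE_LEVELS),
}


@dataclass
class SurveyResponse:
    """One respondent's full record.

    Multi-select answers are sets of level codes; an empty set means the
    question was not answered.  Scalar ``None`` / empty string likewise means
    missing.  "Prefer not to answer" is a level, i.e. an *answered* question.
    """

    respondent_id: str
    submission_timestamp: datetime | None = None
    survey_source: str | None = None
    survey_source_detail: str = ""
    reported_age: int | None = None
    date_of_birth: date | None = None
    gender_identities: set[str] = field(default_factory=set)
    sex_assigned_at_birth: str | None = None
    sexual_orientation: str | None = None
    race_ethnicities: set[str] = field(default_factory=set)
    marital_status: str | None = None
    household_size: int | None = None
    education: str | None = None
    income_bracket: str | None = None
    country_of_residence: str | None = None
    cancer_stage: str | None = None
    cancer_types: set[str] = field(default_factory=set)
    age_at_diagnosis: int | None = None
    time_since_diagnosis: str | None = None
    time_since_treatment: str | None = None
    cancer_care_status: set[str] = field(default_factory=set)
    employment_status: set[str] = field(default_factory=set)
    insurance_types: set[str] = field(default_factory=set)
    tribe_or_territory: bool | None = None
    self_reported_health: str | None = None
    telehealth_comment: str = ""
    final_suggestion: str = ""
    email: str = ""
    first_name: str = ""
    last_name: str = ""
    name_suffix: str = ""
    postal_address: str = ""
    honeypot_value: str = ""
    retyped_word: str = ""
    acknowledgement_checked: bool | None = None

    def is_missing(self, question: str) -> bool:
        """Whether *question* (an inventory item / field name) is unanswered."""
        value = getattr(self, question)
        if value is None:
            return True
        if isinstance(value, (set, frozenset, str)):
            return len(value) == 0
        return False

    def submitted_eastern(self) -> datetime | None:
        ts = self.submission_timestamp
        return None if ts is None else ts.astimezone(EASTERN)


def floor_age(born: date, on: date) -> int:
    """Completed years of age on a given date (birthday arithmetic)."""
    years = on.year - born.year
    if (on.month, on.day) < (born.month, born.day):
        years -= 1
    return years


# ---------------------------------------------------------------------------
# Question inventory (denominator of the missingness rule)
# ---------------------------------------------------------------------------

#: Substantive survey items counted by the >=35% missingness rule.  Identity
#: and incentive fields (name, email, address) and the bot traps are excluded:
#: a respondent declining to identify themselves is not "missing data" in the
#: survey sense.  Fully configurable via QuestionInventory.
DEFAULT_INVENTORY: tuple[str, ...] = (
    "survey_source",
    "reported_age",
    "date_of_birth",
    "gender_identities",
    "sex_assigned_at_birth",
    "sexual_orientation",
    "race_ethnicities",
    "marital_status",
    "household_size",
    "education",
    "income_bracket",
    "country_of_residence",
    "cancer_stage",
    "cancer_types",
    "age_at_diagnosis",
    "time_since_diagnosis",
    "time_since_treatment",
    "cancer_care_status",
    "employment_status",
    "insurance_types",
    "tribe_or_territory",
    "self_reported_health",
    "telehealth_comment",
    "final_suggestion",
)


@dataclass(frozen=True)
class QuestionInventory:
    """The fixed question list over which missingness fractions are defined."""

    questions: tuple[str, ...] = DEFAULT_INVENTORY

    def __post_init__(self) -> None:
        if not self.questions:
            raise ValueError("question inventory must be non-empty")
        unknown = [q for q in self.questions if q not in SurveyResponse.__dataclass_fields__]
        if unknown:
            raise ValueError(f"inventory names unknown fields: {unknown}")

    def __len__(self) -> int:
        return len(self.questions)


def missingness_fraction(
    record: SurveyResponse, inventory: QuestionInventory | None = None
) -> float:
    """Fraction of inventory questions the record left unanswered, in [0, 1]."""
    inv = inventory or QuestionInventory()
    n_missing = sum(record.is_missing(q) for q in inv.questions)
    frac = n_missing / len(inv)
    assert 0.0 <= frac <= 1.0 and math.isfinite(frac)
    return frac


def missing_mask(
    record: SurveyResponse, inventory: QuestionInventory | None = None
) -> dict[str, bool]:
    """Per-question missing/answered flags over the configured inventory."""
    inv = inventory or QuestionInventory()
    return {q: record.is_missing(q) for q in inv.questions}
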