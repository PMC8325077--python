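"""Stage-1 screening: eligibility, missingness and internal contradictions.

The cascade removes, in order: (1) ineligible respondents — living outside
the United States, stage 0 disease, no cancer diagnosis, or only nonmelanoma
skin cancer; (2) records missing >=35% of substantive survey questions;
(3) contradictory gender identities (e.g. simultaneously cisgender male and
cisgender female); (4) sex assigned at birth incompatible with the anatomic
site of the reported cancer (e.g. male at birth with uterine cancer).

Each record is attributed to the FIRST stage it fails, so per-stage removal
counts are disjoint and sum to the total removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .config import (
    DEFAULT_EXCLUSIVE_GENDER_PAIRS,
    DEFAULT_SEX_SITE_MAP,
    ScreeningThresholds,
)
from .schema import QuestionInventory, SurveyResponse, missingness_fraction

__all__ = [
    "EligibilityVerdict",
    "EligibilityScreen",
    "check_ineligible",
    "check_gender_contradiction",
    "check_sex_site_contradiction",
    "screen_cohort",
    "STAGE_ORDER",
]

#: Reason codes in cascade order; "core" ineligibility reasons share stage 1.
STAGE_ORDER: tuple[str, ...] = (
    "ineligible_core",        # non_us_resident | stage_0 | no_cancer_diagnosis
    "nonmelanoma_only",
    "excess_missingness",
    "discordant_gender",
    "discordant_sex_site",
)

_US_NAMES = {
    "united states",
    "united states of america",
    "usa",
    "us",
    "u.s.",
    "u.s.a.",
    "america",
}


@dataclass(frozen=True)
class EligibilityVerdict:
    respondent_id: str
    reasons: frozenset[str] = frozenset()
    #: first failed stage under the cascade ordering, or None if eligible
    removal_stage: str | None = None

    @property
    def eligible(self) -> bool:
        return not self.reasons


def _is_us_resident(record: SurveyResponse) -> bool | None:
    country = record.country_of_residence
    if country is None or not country.strip():
        return None  # unknown — cannot establish non-US residence
    return country.strip().lower() in _US_NAMES


def check_ineligible(record: SurveyResponse) -> frozenset[str]:
    """Core ineligibility reasons plus nonmelanoma-only, as a reason set.

    ``no_cancer_diagnosis`` requires an explicit "none" stage together with an
    empty cancer-type selection; a record that simply skipped both questions
    is handled by the missingness rule, not here.
    """
    reasons: set[str] = set()
    if _is_us_resident(record) is False:
        reasons.add("non_us_resident")
    if record.cancer_stage == "0":
        reasons.add("stage_0")
    if not record.cancer_types and record.cancer_stage == "none":
        reasons.add("no_cancer_diagnosis")
    if record.cancer_types == {"nonmelanoma_skin"}:
        reasons.add("nonmelanoma_only")
    return frozenset(reasons)


def check_gender_contradiction(
    record: SurveyResponse,
    exclusive_pairs: Iterable[frozenset[str]] = DEFAULT_EXCLUSIVE_GENDER_PAIRS,
) -> bool:
    """True iff the gender multi-select contains a mutually exclusive pair."""
    identities = record.gender_identities
    return any(pair <= identities for pair in exclusive_pairs)


def check_sex_site_contradiction(
    record: SurveyResponse,
    incompatibility_map: dict[str, frozenset[str]] | None = None,
) -> bool:
    """True iff a reported cancer site is anatomically impossible for the
    reported sex assigned at birth."""
    imap = incompatibility_map if incompatibility_map is not None else DEFAULT_SEX_SITE_MAP
    sex = record.sex_assigned_at_birth
    if sex is None:
        return False
    incompatible = imap.get(sex, frozenset())
    return bool(record.cancer_types & incompatible)


class EligibilityScreen(BaseEstimator):
    """Scikit-learn-style estimator for the stage-1 cascade.

    ``fit(X)`` takes a cohort (sequence of :class:`SurveyResponse`) and
    computes :attr:`verdicts_` and disjoint :attr:`stage_counts_`;
    ``fit_predict(X)`` returns ``True`` per record for stage-1 survivors.

    Parameters
    ----------
    thresholds : ScreeningThresholds
        Supplies the missingness cutoff (default 0.35).
    inventory : QuestionInventory
        Question list defining the missingness denominator.
    exclusive_gender_pairs, sex_site_map
        Contradiction definitions; see :mod:`surveyscreen.config`.
    """

    def __init__(
        self,
        thresholds: ScreeningThresholds | None = None,
        inventory: QuestionInventory | None = None,
        exclusive_gender_pairs: tuple[frozenset[str], ...] | None = None,
        sex_site_map: dict[str, frozenset[str]] | None = None,
    ):
        self.thresholds = thresholds
        self.inventory = inventory
        self.exclusive_gender_pairs = exclusive_gender_pairs
        self.sex_site_map = sex_site_map

    def _resolve(self):
        return (
            self.thresholds or ScreeningThresholds(),
            self.inventory or QuestionInventory(),
            self.exclusive_gender_pairs
            if self.exclusive_gender_pairs is not None
            else DEFAULT_EXCLUSIVE_GENDER_PAIRS,
            self.sex_site_map if self.sex_site_map is not None else DEFAULT_SEX_SITE_MAP,
        )

    def _verdict(self, record: SurveyResponse) -> EligibilityVerdict:
        thresholds, inventory, pairs, sex_site = self._resolve()
        reasons: set[str] = set(check_ineligible(record))
        if missingness_fraction(record, inventory) >= thresholds.missingness_cutoff:
            reasons.add("excess_missingness")
        if check_gender_contradiction(record, pairs):
            reasons.add("discordant_gender")
        if check_sex_site_contradiction(record, sex_site):
            reasons.add("discordant_sex_site")

        stage = None
        if reasons & {"non_us_resident", "stage_0", "no_cancer_diagnosis"}:
            stage = "ineligible_core"
        elif "nonmelanoma_only" in reasons:
            stage = "nonmelanoma_only"
        elif "excess_missingness" in reasons:
            stage = "excess_missingness"
        elif "discordant_gender" in reasons:
            stage = "discordant_gender"
        elif "discordant_sex_site" in reasons:
            stage = "discordant_sex_site"
        return EligibilityVerdict(
            respondent_id=record.respondent_id,
            reasons=frozenset(reasons),
            removal_stage=stage,
        )

    def fit(self, X: Sequence[SurveyResponse], y=None) -> "EligibilityScreen":
        verdicts = [self._verdict(rec) for rec in X]
        counts = {stage: 0 for stage in STAGE_ORDER}
        for v in verdicts:
            if v.removal_stage is not None:
                counts[v.removal_stage] += 1
        self.verdicts_ = verdicts
        self.stage_counts_ = counts
        self.n_eligible_ = sum(v.removal_stage is None for v in verdicts)
        return self

    def fit_predict(self, X: Sequence[SurveyResponse], y=None) -> list[bool]:
        """Per-record survival flags (True = passes stage 1)."""
        self.fit(X)
        return [v.removal_stage is None for v in self.verdicts_]


def screen_cohort(
    records: Sequence[SurveyResponse],
    thresholds: ScreeningThresholds | None = None,
    incompatibility_map: dict[str, frozenset[str]] | None = None,
    inventory: QuestionInventory | None = None,
    exclusive_gender_pairs: tuple[frozenset[str], ...] | None = None,
) -> tuple[list[EligibilityVerdict], dict[str, int]]:
    """Functional wrapper: verdicts plus disjoint per-stage removal counts."""
    screen = EligibilityScreen(
        thresholds=thresholds,
        inventory=inventory,
        exclusive_gender_pairs=exclusive_gender_pairs,
        sex_site_map=incompatibility_map,
    ).fit(records)
    return screen.verdicts_, screen.stage_counts_
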