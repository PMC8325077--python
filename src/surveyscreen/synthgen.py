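"""Synthetic survey cohorts with planted ground truth.

The generator emits three classes of record:

* **legit** — internally consistent cancer-survivor responses that satisfy no
  elimination rule: consistent age/DOB, plausible cancer history, unique
  well-formed identities, daytime submissions spaced more than five minutes
  apart, sources claimed only after their dissemination dates;
* **ineligible** — otherwise-clean records that instantiate exactly one
  stage-1 removal reason (non-US residence, stage 0, no diagnosis,
  nonmelanoma-only, >=35% missingness, contradictory gender, sex/site
  contradiction);
* **fraud** — records planted with two or more suspicious indicators whose
  per-indicator marginal totals are hit *exactly* (default: the study-scale
  marginals), or, in probabilistic mode, with each of a set of record-local
  indicators planted independently with a common probability.

Planting is constructive: a record planted SOURCE_INCONGRUENT really does
claim a source dated after its submission; a record *not* planted an
indicator is built so the corresponding detector cannot fire (e.g. clean
submissions sit on a 6-minute grid so no ten-long run with <=5-minute gaps
can arise).  That makes the pipeline-vs-truth comparison an exact-recovery
test rather than a statistical one.

Timeline layout (all US Eastern): bursts and night submissions occupy
October 9-11, 2020; pre-dissemination singletons (source incongruence
without suspicious timing) sit on October 8 and 12; everything else follows
from October 13 on a 6-minute daytime grid.  This mirrors the phenomenology
of a public survey link briefly exposed on social media: the fraudulent
wave lands in a narrow early window, legitimate email-recruited responses
trickle in afterwards.

All randomness flows through one ``numpy.random.Generator`` seeded from
``GeneratorConfig.seed``; the same config yields a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Iterator, Sequence

import numpy as np

from .config import ConfigurationError, Lexicons, ScreenConfig
from .indicators import INDICATOR_CODES
from .pipeline import EliminationDecision
from .schema import EASTERN, SurveyResponse

__all__ = [
    "GeneratorConfig",
    "CohortTruth",
    "DetectionReport",
    "generate_cohort",
    "plant_burst",
    "evaluate_detection",
    "paper_scale_config",
]

#: Study-scale per-indicator marginal counts among the 1081 eliminated records.
STUDY_INDICATOR_COUNTS: dict[str, int] = {
    "AGE_DISCORD": 250,
    "RARE_CANCER_YOUNG": 283,
    "SOURCE_INCONGRUENT": 820,
    "OFFTOPIC_TEXT": 56,
    "DUP_TELEHEALTH": 34,
    "DUP_SUGGESTION": 107,
    "DUP_EMAIL": 20,
    "TIMELINE_DX_LT2_TX_2TO5": 11,
    "TIMELINE_DX_LE5_TX_GT5": 57,
    "SUSPICIOUS_TIMING": 986,
    "SUSPICIOUS_EMAIL_ADDRESS": 166,
    "SUSPICIOUS_NAME": 78,
}

#: Study-scale disjoint stage-1 planting counts (83 core ineligible split
#: across its three separable reasons).
STUDY_STAGE1_COUNTS: dict[str, int] = {
    "non_us_resident": 28,
    "stage_0": 28,
    "no_cancer_diagnosis": 27,
    "nonmelanoma_only": 46,
    "excess_missingness": 149,
    "discordant_gender": 12,
    "discordant_sex_site": 37,
}

#: Indicator pairs that cannot be planted on one record without breaking the
#: exactness of some other planting (or being logically impossible).
_INCOMPATIBLE_PAIRS: tuple[frozenset[str], ...] = (
    frozenset({"TIMELINE_DX_LT2_TX_2TO5", "TIMELINE_DX_LE5_TX_GT5"}),
    frozenset({"OFFTOPIC_TEXT", "DUP_TELEHEALTH"}),
    frozenset({"DUP_EMAIL", "SUSPICIOUS_EMAIL_ADDRESS"}),
)

_RECORD_LOCAL_CODES: tuple[str, ...] = (
    "AGE_DISCORD",
    "RARE_CANCER_YOUNG",
    "OFFTOPIC_TEXT",
    "SUSPICIOUS_EMAIL_ADDRESS",
    "SUSPICIOUS_NAME",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort parameters; defaults are the study-scale conditions."""

    seed: int = 0
    n_legit: int = 569
    n_fraud: int = 1081
    stage1_counts: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_STAGE1_COUNTS)
    )
    indicator_counts: dict[str, int] = field(
        default_factory=lambda: dict(STUDY_INDICATOR_COUNTS)
    )
    #: probabilistic mode: plant each of `probabilistic_indicators`
    #: independently with this probability (overrides indicator_counts)
    indicator_probability: float | None = None
    probabilistic_indicators: tuple[str, ...] = _RECORD_LOCAL_CODES
    burst_size: int = 12
    burst_gap: timedelta = timedelta(minutes=2)
    night_fraction: float = 0.08
    legit_age_mean: float = 55.9
    legit_age_sd: float = 13.1
    fraud_age_mean: float = 41.4
    fraud_age_sd: float = 8.2
    survey_open: date = date(2020, 10, 8)
    email_dissemination: date = date(2020, 10, 13)

    def validate(self) -> None:
        if self.n_legit < 0 or self.n_fraud < 0:
            raise ConfigurationError("class sizes must be non-negative")
        if any(v < 0 for v in self.stage1_counts.values()):
            raise ConfigurationError("stage-1 planting counts must be non-negative")
        if self.indicator_probability is not None:
            if not 0.0 <= self.indicator_probability <= 1.0:
                raise ConfigurationError("indicator_probability must lie in [0, 1]")
        else:
            unknown = set(self.indicator_counts) - set(INDICATOR_CODES)
            if unknown:
                raise ConfigurationError(f"unknown indicator codes: {sorted(unknown)}")
            if any(v < 0 for v in self.indicator_counts.values()):
                raise ConfigurationError("indicator counts must be non-negative")
            if self.n_fraud:
                if max(self.indicator_counts.values(), default=0) > self.n_fraud:
                    raise ConfigurationError("an indicator count exceeds n_fraud")
                if sum(self.indicator_counts.values()) < 2 * self.n_fraud:
                    raise ConfigurationError(
                        "indicator counts cannot give every fraud record >=2 indicators"
                    )
                if self.indicator_counts.get("DUP_EMAIL", 0) == 1:
                    raise ConfigurationError("DUP_EMAIL needs >=2 records to duplicate")
                for fld in ("DUP_TELEHEALTH", "DUP_SUGGESTION"):
                    if self.indicator_counts.get(fld, 0) == 1:
                        raise ConfigurationError(f"{fld} needs >=2 records to duplicate")
        if not 0.0 <= self.night_fraction <= 1.0:
            raise ConfigurationError("night_fraction must lie in [0, 1]")
        if self.burst_size < 1:
            raise ConfigurationError("burst_size must be >=1")


def paper_scale_config(seed: int = 0) -> GeneratorConfig:
    """The shipped study-scale configuration (1977 = 569 + 327 + 1081)."""
    return GeneratorConfig(seed=seed)


def load_generator_config(path) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from YAML (see
    ``resources/paper_scale.yaml`` for the shipped study-scale file)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "burst_gap_minutes" in raw:
        raw["burst_gap"] = timedelta(minutes=float(raw.pop("burst_gap_minutes")))
    if "survey_open" in raw and isinstance(raw["survey_open"], str):
        raw["survey_open"] = date.fromisoformat(raw["survey_open"])
    if "email_dissemination" in raw and isinstance(raw["email_dissemination"], str):
        raw["email_dissemination"] = date.fromisoformat(raw["email_dissemination"])
    if "probabilistic_indicators" in raw:
        raw["probabilistic_indicators"] = tuple(raw["probabilistic_indicators"])
    cfg = GeneratorConfig(**raw)
    cfg.validate()
    return cfg


@dataclass(frozen=True)
class CohortTruth:
    """Planted ground truth, keyed by respondent id."""

    clazz: dict[str, str]                      # "legit" | "fraud" | "ineligible"
    stage1_reason: dict[str, str]              # ineligible records only
    planted_indicators: dict[str, frozenset[str]]  # fraud records only

    def n_class(self, name: str) -> int:
        return sum(c == name for c in self.clazz.values())


@dataclass(frozen=True)
class DetectionReport:
    sensitivity: float
    specificity: float
    per_indicator: dict[str, dict[str, int]]  # code -> {tp, fp, fn, tn}


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def plant_burst(base: datetime, size: int, gap: timedelta) -> list[datetime]:
    """Arithmetic run of `size` timestamps spaced `gap` apart."""
    if size < 1:
        raise ConfigurationError("burst size must be >=1")
    return [base + i * gap for i in range(size)]


def _assign_indicator_sets(
    n: int, counts: dict[str, int], rng: np.random.Generator
) -> list[set[str]]:
    """Give each of n records >=2 indicators with exact marginal counts.

    Greedy largest-remaining-first for the first two slots per record, then
    leftovers spread over records lacking the indicator; incompatible pairs
    are never co-planted.
    """
    codes = [c for c in INDICATOR_CODES if counts.get(c, 0) > 0]
    remaining = {c: counts[c] for c in codes}
    sets: list[set[str]] = [set() for _ in range(n)]

    def compatible(s: set[str], code: str) -> bool:
        return not any(
            pair <= (s | {code}) for pair in _INCOMPATIBLE_PAIRS
        )

    for s in sets:
        for _ in range(2):
            choices = sorted(
                (c for c in codes if remaining[c] > 0 and c not in s and compatible(s, c)),
                key=lambda c: (-remaining[c], c),
            )
            if not choices:
                raise ConfigurationError(
                    "infeasible indicator counts: cannot give every record two "
                    "compatible indicators"
                )
            pick = choices[0]
            s.add(pick)
            remaining[pick] -= 1

    # leftovers: prefer co-planting SOURCE_INCONGRUENT with SUSPICIOUS_TIMING
    # (keeps the pre-dissemination singleton window small)
    for code in sorted(codes, key=lambda c: (-remaining[c], c)):
        order = sorted(
            range(n),
            key=lambda i: (
                0 if ("SUSPICIOUS_TIMING" in sets[i]) == (code == "SOURCE_INCONGRUENT") else 1,
                len(sets[i]),
                i,
            ),
        )
        for i in order:
            if remaining[code] == 0:
                break
            if code not in sets[i] and compatible(sets[i], code):
                sets[i].add(code)
                remaining[code] -= 1
        if remaining[code] > 0:
            raise ConfigurationError(f"could not place all plantings of {code}")

    rng.shuffle(sets)
    return sets


class _SlotAllocator:
    """Disjoint Eastern-time submission slots per category.

    Clean daytime slots sit on a 6-minute grid (burst-proof and outside the
    night window); bursts get their own reserved days with >=10-minute
    inter-burst gaps; night slots run 00:30-03:50.
    """

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg

    @staticmethod
    def _grid(days: Iterator[date], start: time, end: time, step: timedelta):
        for day in days:
            t = datetime.combine(day, start, tzinfo=EASTERN)
            stop = datetime.combine(day, end, tzinfo=EASTERN)
            while t < stop:
                yield t
                t += step

    def burst_timestamps(self, n_records: int) -> list[datetime]:
        """Timestamps covering n_records in bursts of >=burst_min_run size."""
        cfg = self.cfg
        sizes: list[int] = []
        left = n_records
        while left > 0:
            take = min(cfg.burst_size, left)
            if 0 < left - take < 10:  # fold a short tail into the last burst
                take = left
            sizes.append(take)
            left -= take
        out: list[datetime] = []
        day = cfg.survey_open + timedelta(days=1)  # Oct 9
        t = datetime.combine(day, time(8, 0), tzinfo=EASTERN)
        day_end = datetime.combine(day, time(22, 0), tzinfo=EASTERN)
        for size in sizes:
            span = (size - 1) * cfg.burst_gap
            if t + span > day_end:
                day += timedelta(days=1)
                t = datetime.combine(day, time(8, 0), tzinfo=EASTERN)
                day_end = datetime.combine(day, time(22, 0), tzinfo=EASTERN)
            out.extend(plant_burst(t, size, cfg.burst_gap))
            t = out[-1] + timedelta(minutes=10)
        self.last_burst_day = day
        return out

    def night_slots(self, n: int, night_days: Sequence[date]) -> list[datetime]:
        slots = list(
            self._grid(iter(night_days), time(0, 30), time(3, 50), timedelta(minutes=6))
        )
        if len(slots) < n:
            raise ConfigurationError("not enough night-window slots; shrink night_fraction")
        return slots[:n]

    def predissemination_slots(self, n: int, burst_days: set[date]) -> list[datetime]:
        cfg = self.cfg
        days = [
            cfg.survey_open + timedelta(days=k)
            for k in range((cfg.email_dissemination - cfg.survey_open).days)
        ]
        days = [d for d in days if d not in burst_days]
        slots = list(self._grid(iter(days), time(7, 0), time(22, 0), timedelta(minutes=6)))
        if len(slots) < n:
            raise ConfigurationError(
                "not enough pre-dissemination daytime slots for source-incongruent "
                "records outside bursts"
            )
        return slots[:n]

    def normal_slots(self, n: int) -> list[datetime]:
        def days() -> Iterator[date]:
            d = self.cfg.email_dissemination
            while True:
                yield d
                d += timedelta(days=1)

        out: list[datetime] = []
        for ts in self._grid(days(), time(7, 0), time(22, 0), timedelta(minutes=6)):
            out.append(ts)
            if len(out) == n:
                return out
        return out


# ---------------------------------------------------------------------------
# Record factories
# ---------------------------------------------------------------------------

_SAFE_CANCERS = ("breast", "colorectal", "thyroid", "melanoma", "blood", "other")
_LATE_ONSET = ("lung", "kidney", "bladder")
_STREETS = (
    "Oak", "Maple", "Cedar", "Elm", "Walnut", "Chestnut", "Willow", "Birch",
    "Spruce", "Sycamore", "Juniper", "Magnolia", "Dogwood", "Hickory",
)
_STREET_TYPES = ("St", "Ave", "Rd", "Ln", "Dr", "Ct")
_CITIES = (
    ("Springfield", "IL", "62704"), ("Riverton", "VA", "22150"),
    ("Fairview", "OH", "44126"), ("Georgetown", "TX", "78626"),
    ("Madison", "WI", "53703"), ("Clinton", "NC", "28328"),
    ("Salem", "OR", "97301"), ("Greenville", "SC", "29601"),
)
_NORMAL_SOURCES = (
    ("coc_email", 0.66), ("community_partner", 0.12), ("accc_exchange", 0.06),
    ("aosw_listserv", 0.06), ("gwu_newsletter", 0.06), ("other", 0.04),
)
_TELE_TEMPLATES = (
    "My oncologist listened carefully during the video visit",
    "The telehealth appointment with my care team went smoothly",
    "I appreciated talking to my nurse about treatment from home",
    "Seeing my doctor by video saved me a long drive to the clinic",
    "My provider explained my scan results clearly over telehealth",
)
_SUGG_TEMPLATES = (
    "Please keep offering evening telehealth appointments for survivors",
    "It would help to have a nurse navigator follow up after each visit",
    "Offer clearer instructions for joining the video appointment",
    "Keep supporting patients who live far from the cancer clinic",
    "More help understanding insurance coverage for treatment would help",
)
_IT_TEMPLATES = (
    "Great software and a very nice user interface overall",
    "The website loaded fast and the network bandwidth was impressive",
    "Excellent browser compatibility and smooth login workflow",
    "The server response and database speed were outstanding",
)


class _CohortBuilder:
    def __init__(self, cfg: GeneratorConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.lex = Lexicons.bundled()
        # name pools filtered so clean identities can never trip the name or
        # email heuristics (no crossover substrings, short alnum runs)
        self.female = [n for n in self.lex.given_names_female if len(n) <= 9]
        self.male = [n for n in self.lex.given_names_male if len(n) <= 9]
        givens = self.lex.given_names
        self.surnames = [n for n in self.lex.surnames if len(n) <= 9]
        self.flip_surnames = [n for n in self.surnames if n not in givens]
        self.flip_givens = [n for n in self.female + self.male if n not in set(self.lex.surnames)]
        self._surname_set = set(self.lex.surnames)
        self._calendar = ScreenConfig().calendar
        self._uid = 0
        self._email_seen: set[str] = set()

    # -- identity helpers ---------------------------------------------------

    def _next_uid(self) -> int:
        self._uid += 1
        return self._uid

    def _clean_name(self, sex: str) -> tuple[str, str]:
        pool = self.female if sex == "female" else self.male
        while True:
            first = pool[int(self.rng.integers(len(pool)))]
            last = self.surnames[int(self.rng.integers(len(self.surnames)))]
            if first == last or first in last or last in first:
                continue
            if first in self._surname_set:  # could read as flipped
                continue
            return first.capitalize(), last.capitalize()

    def _clean_email(self, first: str, last: str) -> str:
        email = f"{first.lower()}.{last.lower()}.{self._next_uid()}@example.com"
        assert email not in self._email_seen
        self._email_seen.add(email)
        return email

    def _clean_address(self) -> str:
        num = int(self.rng.integers(10, 9900))
        street = _STREETS[int(self.rng.integers(len(_STREETS)))]
        stype = _STREET_TYPES[int(self.rng.integers(len(_STREET_TYPES)))]
        city, st, zipc = _CITIES[int(self.rng.integers(len(_CITIES)))]
        return f"{num} {street} {stype}, {city}, {st} {zipc}"

    def _random_email(self) -> str:
        # >=10-char local-part run mixing digits and letters
        alphabet = "abcdefghjkmnpqrstuvwxyz23456789"
        while True:
            chars = [alphabet[int(i)] for i in self.rng.integers(0, len(alphabet), 12)]
            local = "".join(chars)
            if any(c.isdigit() for c in local) and any(c.isalpha() for c in local):
                email = f"{local}@mailbox.com"
                if email not in self._email_seen:
                    self._email_seen.add(email)
                    return email

    def _unique_text(self, templates: Sequence[str]) -> str:
        base = templates[int(self.rng.integers(len(templates)))]
        return f"{base}, note {self._next_uid()}."

    def _consistent_dob(self, age: int, submitted: datetime) -> date:
        m = int(self.rng.integers(1, 13))
        d = int(self.rng.integers(1, 29))
        sub = submitted.astimezone(EASTERN).date()
        year = sub.year - age if (m, d) <= (sub.month, sub.day) else sub.year - age - 1
        return date(year, m, d)

    def _draw_age(self, mean: float, sd: float) -> int:
        while True:
            a = int(round(self.rng.normal(mean, sd)))
            if 18 <= a <= 95:
                return a

    def _draw_source(self, submitted: datetime) -> str:
        sub = submitted.astimezone(EASTERN).date()
        names = [s for s, _ in _NORMAL_SOURCES]
        probs = np.array([p for _, p in _NORMAL_SOURCES])
        cal = self._calendar
        valid = [
            i for i, s in enumerate(names)
            if cal.earliest[s] is None or cal.earliest[s] <= sub
        ]
        probs = probs[valid] / probs[valid].sum()
        return names[valid[int(self.rng.choice(len(valid), p=probs))]]

    # -- base records -------------------------------------------------------

    def _base_record(
        self, rid: str, submitted: datetime, clazz: str, age: int | None = None
    ) -> SurveyResponse:
        cfg = self.cfg
        rng = self.rng
        legit = clazz != "fraud"
        if age is None:
            age = self._draw_age(
                cfg.legit_age_mean if legit else cfg.fraud_age_mean,
                cfg.legit_age_sd if legit else cfg.fraud_age_sd,
            )
        female = bool(rng.random() < (0.70 if legit else 0.45))
        sex = "female" if female else "male"
        gender = {"cisgender_female"} if female else {"cisgender_male"}
        first, last = self._clean_name(sex)

        # cancer type compatible with sex and (if <40) not late-onset
        pool = list(_SAFE_CANCERS)
        if female:
            pool.append("uterine_cervical")
        if age >= 40:
            pool.extend(_LATE_ONSET)
            if not female:
                pool.append("prostate")
        weights = np.array(
            [5.0 if (legit and c == "breast") else 1.0 for c in pool]
        )
        ctype = pool[int(rng.choice(len(pool), p=weights / weights.sum()))]

        dx = ("<2", "2-5", ">5")[int(rng.integers(3))]
        tx_options = {"<2": ("<2",), "2-5": ("<2", "2-5"), ">5": ("<2", "2-5", ">5")}[dx]
        tx = tx_options[int(rng.integers(len(tx_options)))]
        years_since = {"<2": 1, "2-5": 3, ">5": 8}[dx]
        age_dx = max(18, age - years_since)

        return SurveyResponse(
            respondent_id=rid,
            submission_timestamp=submitted,
            survey_source=self._draw_source(submitted),
            reported_age=age,
            date_of_birth=self._consistent_dob(age, submitted),
            gender_identities=gender,
            sex_assigned_at_birth=sex,
            sexual_orientation="straight" if rng.random() < 0.9 else "lgbq_two_spirit",
            race_ethnicities={
                ("white", "black", "asian", "hispanic_latinx")[int(rng.choice(4, p=(0.68, 0.16, 0.06, 0.10)))]
            },
            marital_status=("married_partnered", "single", "divorced_separated", "widowed")[
                int(rng.choice(4, p=(0.7, 0.15, 0.1, 0.05)))
            ],
            household_size=max(1, int(round(rng.normal(2.6 if legit else 3.3, 1.1)))),
            education=("some_college", "completed_4_year_degree", "graduate_school",
                       "high_school_ged_vocational")[int(rng.integers(4))],
            income_bracket=("25001_50000", "50001_75000", "75001_100000",
                            "gt_100000", "lt_25000")[int(rng.integers(5))],
            country_of_residence="United States",
            cancer_stage=("I", "II", "III", "IV", "unknown")[int(rng.choice(5, p=(0.35, 0.3, 0.17, 0.1, 0.08)))],
            cancer_types={ctype},
            age_at_diagnosis=age_dx,
            time_since_diagnosis=dx,
            time_since_treatment=tx,
            cancer_care_status={("remission_or_ned", "chronic", "none_apply")[int(rng.choice(3, p=(0.75, 0.18, 0.07)))]},
            employment_status={("paid_work", "retired", "unemployed", "unpaid_work")[int(rng.integers(4))]},
            insurance_types={("private", "medicare", "medicaid")[int(rng.choice(3, p=(0.55, 0.3, 0.15)))]},
            tribe_or_territory=bool(rng.random() < (0.07 if legit else 0.38)),
            self_reported_health=("excellent_very_good", "good", "fair", "poor")[
                int(rng.choice(4, p=(0.3, 0.4, 0.2, 0.1)))
            ],
            telehealth_comment=self._unique_text(_TELE_TEMPLATES),
            final_suggestion=self._unique_text(_SUGG_TEMPLATES),
            email=self._clean_email(first, last),
            first_name=first,
            last_name=last,
            name_suffix="",
            postal_address=self._clean_address(),
            honeypot_value="",
            retyped_word="telehealth",
            acknowledgement_checked=True,
        )

    # -- plantings ----------------------------------------------------------

    def _plant_stage1(self, rec: SurveyResponse, reason: str) -> SurveyResponse:
        rng = self.rng
        if reason == "non_us_resident":
            return replace(rec, country_of_residence="Canada")
        if reason == "stage_0":
            return replace(rec, cancer_stage="0")
        if reason == "no_cancer_diagnosis":
            return replace(
                rec,
                cancer_types=set(),
                cancer_stage="none",
                age_at_diagnosis=None,
                time_since_diagnosis=None,
                time_since_treatment=None,
                cancer_care_status={"none_apply"},
            )
        if reason == "nonmelanoma_only":
            return replace(rec, cancer_types={"nonmelanoma_skin"})
        if reason == "excess_missingness":
            return replace(
                rec,
                sexual_orientation=None,
                race_ethnicities=set(),
                marital_status=None,
                household_size=None,
                education=None,
                income_bracket=None,
                employment_status=set(),
                insurance_types=set(),
                self_reported_health=None,
                telehealth_comment="",
                final_suggestion="",
            )  # 11 of 24 inventory items missing (45.8% >= 35%)
        if reason == "discordant_gender":
            return replace(rec, gender_identities={"cisgender_male", "cisgender_female"})
        if reason == "discordant_sex_site":
            return replace(
                rec,
                sex_assigned_at_birth="male",
                gender_identities={"cisgender_male"},
                cancer_types={"uterine_cervical"},
            )
        raise ConfigurationError(f"unknown stage-1 reason {reason!r}")

    def _plant_indicators(self, rec: SurveyResponse, planted: frozenset[str]) -> SurveyResponse:
        """Mutate a clean base record so exactly the planted record-local
        indicators fire (cohort-level plantings are handled by the caller)."""
        rng = self.rng
        if "RARE_CANCER_YOUNG" in planted:
            # the caller routed an under-40 age draw to this record
            assert rec.reported_age is not None and rec.reported_age < 40
            rec = replace(
                rec,
                cancer_types={_LATE_ONSET[int(rng.integers(len(_LATE_ONSET)))]},
                age_at_diagnosis=max(18, rec.reported_age - 2),
            )
        if "AGE_DISCORD" in planted:
            if rng.random() < 0.3:
                dob = rec.submission_timestamp.astimezone(EASTERN).date().replace(month=1, day=1)
                rec = replace(rec, date_of_birth=dob)  # "born this year"
            else:
                shift = int(rng.integers(5, 25))
                rec = replace(rec, date_of_birth=rec.date_of_birth.replace(
                    year=rec.date_of_birth.year - shift))
        if "SOURCE_INCONGRUENT" in planted:
            rec = replace(rec, survey_source="coc_email")  # timestamp < Oct 13 by slot
        if "OFFTOPIC_TEXT" in planted:
            rec = replace(rec, telehealth_comment=self._unique_text(_IT_TEMPLATES))
        if "TIMELINE_DX_LT2_TX_2TO5" in planted:
            rec = replace(rec, time_since_diagnosis="<2", time_since_treatment="2-5")
        if "TIMELINE_DX_LE5_TX_GT5" in planted:
            dx = ("<2", "2-5")[int(rng.integers(2))]
            rec = replace(rec, time_since_diagnosis=dx, time_since_treatment=">5")
        if "SUSPICIOUS_EMAIL_ADDRESS" in planted:
            if rng.random() < 0.6:
                rec = replace(rec, email=self._random_email())
            else:
                rec = replace(rec, postal_address='"The Warehouse" 1 Main')
        if "SUSPICIOUS_NAME" in planted:
            style = rng.random()
            if style < 0.5 and self.flip_surnames and self.flip_givens:
                first = self.flip_surnames[int(rng.integers(len(self.flip_surnames)))]
                last = self.flip_givens[int(rng.integers(len(self.flip_givens)))]
                rec = replace(rec, first_name=first.capitalize(), last_name=last.capitalize())
            else:
                rec = replace(rec, name_suffix=f"Jr{int(rng.integers(10))}")
        return rec

    # -- assembly -----------------------------------------------------------

    def build(self) -> tuple[list[SurveyResponse], CohortTruth]:
        cfg = self.cfg
        rng = self.rng

        if cfg.indicator_probability is not None:
            p = cfg.indicator_probability
            planted_sets = [
                {c for c in cfg.probabilistic_indicators if rng.random() < p}
                for _ in range(cfg.n_fraud)
            ]
        else:
            planted_sets = (
                _assign_indicator_sets(cfg.n_fraud, cfg.indicator_counts, rng)
                if cfg.n_fraud
                else []
            )

        timing_idx = [i for i, s in enumerate(planted_sets) if "SUSPICIOUS_TIMING" in s]
        source_only_idx = [
            i
            for i, s in enumerate(planted_sets)
            if "SOURCE_INCONGRUENT" in s and "SUSPICIOUS_TIMING" not in s
        ]
        normal_fraud_idx = [
            i
            for i in range(cfg.n_fraud)
            if i not in set(timing_idx) and i not in set(source_only_idx)
        ]

        allocator = _SlotAllocator(cfg)
        n_night = int(round(cfg.night_fraction * len(timing_idx)))
        n_burst = len(timing_idx) - n_night
        if 0 < n_burst < 10:  # too few for a run; the night window still fires
            n_night, n_burst = len(timing_idx), 0
        burst_ts = allocator.burst_timestamps(n_burst) if n_burst else []
        burst_days = {
            (cfg.survey_open + timedelta(days=1) + timedelta(days=k))
            for k in range(
                ((allocator.last_burst_day if n_burst else cfg.survey_open)
                 - cfg.survey_open).days
            )
        }
        night_days = sorted(burst_days) or [cfg.survey_open + timedelta(days=1)]
        night_ts = allocator.night_slots(n_night, night_days) if n_night else []
        predis_ts = allocator.predissemination_slots(len(source_only_idx), burst_days)
        n_normal = cfg.n_legit + sum(cfg.stage1_counts.values()) + len(normal_fraud_idx)
        normal_ts = allocator.normal_slots(n_normal)
        rng.shuffle(normal_ts)

        fraud_ts: dict[int, datetime] = {}
        for i, ts in zip(timing_idx, burst_ts + night_ts):
            fraud_ts[i] = ts
        for i, ts in zip(source_only_idx, predis_ts):
            fraud_ts[i] = ts
        for i in normal_fraud_idx:
            fraud_ts[i] = normal_ts.pop()

        records: list[SurveyResponse] = []
        clazz: dict[str, str] = {}
        stage1_reason: dict[str, str] = {}
        planted_ind: dict[str, frozenset[str]] = {}
        serial = 0

        def next_id() -> str:
            nonlocal serial
            serial += 1
            return f"R{serial:05d}"

        # fraud ages: draw the whole class profile first and route the
        # under-40 draws to rare-cancer plantings, so plantings do not bias
        # the class age distribution
        cutoff = 40
        age_draws = [
            self._draw_age(cfg.fraud_age_mean, cfg.fraud_age_sd)
            for _ in range(cfg.n_fraud)
        ]
        young = [a for a in age_draws if a < cutoff]
        old = [a for a in age_draws if a >= cutoff]
        fraud_ages: list[int] = []
        for planted in planted_sets:
            if "RARE_CANCER_YOUNG" in planted:
                fraud_ages.append(young.pop() if young else int(rng.integers(20, cutoff)))
            else:
                fraud_ages.append(old.pop() if old else young.pop())

        # fraud records
        dup_groups: dict[str, list[int]] = {"DUP_TELEHEALTH": [], "DUP_SUGGESTION": [], "DUP_EMAIL": []}
        fraud_records: list[SurveyResponse] = []
        for i, planted in enumerate(planted_sets):
            rid = next_id()
            rec = self._base_record(rid, fraud_ts[i], "fraud", age=fraud_ages[i])
            if "SOURCE_INCONGRUENT" not in planted and rec.submitted_eastern().date() < cfg.email_dissemination:
                # burst/night record not planted incongruent: claim a source
                # already disseminated by its submission date
                rec = replace(rec, survey_source="community_partner")
            rec = self._plant_indicators(rec, frozenset(planted))
            for code in dup_groups:
                if code in planted:
                    dup_groups[code].append(len(fraud_records))
            fraud_records.append(rec)
            clazz[rid] = "fraud"
            planted_ind[rid] = frozenset(planted)

        # realise duplicate groups: chunk into pairs (last chunk a triple)
        def chunks(idx: list[int]) -> list[list[int]]:
            if len(idx) < 2:
                if idx:
                    raise ConfigurationError("a duplicate indicator needs >=2 records")
                return []
            out = [idx[k : k + 2] for k in range(0, len(idx) - (len(idx) % 2), 2)]
            if len(idx) % 2:
                out[-1] = out[-1] + [idx[-1]]
            return out

        for g, members in enumerate(chunks(dup_groups["DUP_TELEHEALTH"])):
            text = f"The video call with the clinic team worked well for me, group {g}."
            for m in members:
                fraud_records[m] = replace(fraud_records[m], telehealth_comment=text)
        for g, members in enumerate(chunks(dup_groups["DUP_SUGGESTION"])):
            text = f"Keep the telehealth option for all follow-up visits please, group {g}."
            for m in members:
                fraud_records[m] = replace(fraud_records[m], final_suggestion=text)
        for g, members in enumerate(chunks(dup_groups["DUP_EMAIL"])):
            email = f"shared.responder.{g}@example.com"
            for m in members:
                fraud_records[m] = replace(fraud_records[m], email=email)

        records.extend(fraud_records)

        # ineligible records
        for reason, count in cfg.stage1_counts.items():
            for _ in range(count):
                rid = next_id()
                rec = self._base_record(rid, normal_ts.pop(), "ineligible")
                records.append(self._plant_stage1(rec, reason))
                clazz[rid] = "ineligible"
                stage1_reason[rid] = reason

        # legit records
        for _ in range(cfg.n_legit):
            rid = next_id()
            records.append(self._base_record(rid, normal_ts.pop(), "legit"))
            clazz[rid] = "legit"

        order = rng.permutation(len(records))
        records = [records[i] for i in order]
        return records, CohortTruth(
            clazz=clazz, stage1_reason=stage1_reason, planted_indicators=planted_ind
        )


def generate_cohort(config: GeneratorConfig) -> tuple[list[SurveyResponse], CohortTruth]:
    """Deterministically generate a cohort and its planted ground truth."""
    return _CohortBuilder(config).build()


def evaluate_detection(
    decisions: Sequence[EliminationDecision], truth: CohortTruth
) -> DetectionReport:
    """Sensitivity/specificity of the pipeline against planted classes.

    Sensitivity counts fraud records that were excluded (any stage);
    specificity counts legit records retained.  Per-indicator confusion is
    tallied over records that were actually profiled (stage-1 survivors).
    """
    by_id = {d.respondent_id: d for d in decisions}
    if set(by_id) != set(truth.clazz):
        raise ValueError("decisions and truth cover different respondent ids")

    n_fraud = truth.n_class("fraud")
    n_legit = truth.n_class("legit")
    sens = (
        sum(1 for rid, c in truth.clazz.items() if c == "fraud" and by_id[rid].excluded)
        / n_fraud
        if n_fraud
        else float("nan")
    )
    spec = (
        sum(1 for rid, c in truth.clazz.items() if c == "legit" and by_id[rid].retained)
        / n_legit
        if n_legit
        else float("nan")
    )

    per_indicator: dict[str, dict[str, int]] = {}
    profiled = [
        d for d in decisions if d.outcome in ("retained", "removed_indicators")
    ]
    for code in INDICATOR_CODES:
        tp = fp = fn = tn = 0
        for d in profiled:
            planted = code in truth.planted_indicators.get(d.respondent_id, frozenset())
            fired = code in d.fired_indicators
            tp += planted and fired
            fp += fired and not planted
            fn += planted and not fired
            tn += not planted and not fired
        per_indicator[code] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return DetectionReport(sensitivity=sens, specificity=spec, per_indicator=per_indicator)
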