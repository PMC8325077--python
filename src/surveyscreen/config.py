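"""Screening configuration: thresholds, dissemination calendar, rule maps.

Every numeric constant a screening rule uses lives in
:class:`ScreeningThresholds` so the whole cascade is re-parameterisable from a
single YAML file.  Defaults are the published study's values: 35% missingness
cutoff, elimination at two or more suspicious indicators, one-year age
discordance, age-40 rare-cancer cutoff, bursts of at least ten submissions
within five minutes of each other, the midnight-to-4AM Eastern night window,
and ten-character random runs in email local parts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, time, timedelta

import yaml

from .schema import CANCER_TYPE_LEVELS, SOURCE_LEVELS


class ConfigurationError(ValueError):
    """Raised when a config bundle is incomplete or inconsistent."""


@dataclass(frozen=True)
class ScreeningThresholds:
    missingness_cutoff: float = 0.35
    indicator_elimination_count: int = 2
    age_discordance_years: int = 1
    young_age_cutoff: int = 40
    burst_min_run: int = 10
    burst_max_gap: timedelta = timedelta(minutes=5)
    night_window_start: time = time(0, 0)   # Eastern clock time, inclusive
    night_window_end: time = time(4, 0)     # exclusive
    random_run_min_length: int = 10
    duplicate_text_min_length: int = 15
    address_min_tokens: int = 4

    def __post_init__(self) -> None:
        positive = (
            ("missingness_cutoff", self.missingness_cutoff),
            ("indicator_elimination_count", self.indicator_elimination_count),
            ("age_discordance_years", self.age_discordance_years),
            ("young_age_cutoff", self.young_age_cutoff),
            ("burst_min_run", self.burst_min_run),
            ("random_run_min_length", self.random_run_min_length),
            ("duplicate_text_min_length", self.duplicate_text_min_length),
            ("address_min_tokens", self.address_min_tokens),
        )
        for name, value in positive:
            if value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        if self.burst_max_gap <= timedelta(0):
            raise ConfigurationError("burst_max_gap must be strictly positive")


@dataclass(frozen=True)
class DisseminationCalendar:
    """Earliest legitimate calendar date (US Eastern) per survey source.

    A source mapped to ``None`` is explicitly "unknown": the source-incongruence
    rule can never fire for it.  Sources appearing in data but absent from the
    mapping are an error — unknowns must be declared, never silent.
    """

    earliest: dict[str, date | None] = field(
        default_factory=lambda: {
            "coc_email": date(2020, 10, 13),
            "community_partner": date(2020, 10, 8),
            "accc_exchange": date(2020, 10, 8),
            "aosw_listserv": date(2020, 10, 8),
            "gwu_newsletter": date(2020, 10, 13),
            "social_media": date(2020, 10, 8),
            "other": None,
        }
    )

    def earliest_date(self, source: str | None) -> date | None:
        if source is None:
            return None
        if source not in self.earliest:
            raise ConfigurationError(
                f"survey source {source!r} has no dissemination-calendar entry; "
                "map it to a date or explicitly to null"
            )
        return self.earliest[source]

    def validate_sources(self, sources: set[str]) -> None:
        missing = sorted(s for s in sources if s not in self.earliest)
        if missing:
            raise ConfigurationError(
                f"sources missing from dissemination calendar: {missing}"
            )


#: Mutually exclusive gender-identity pairs.  The published example is holding
#: both cisgender male and cisgender female status; same-axis cis/trans pairs
#: are contradictions for the same reason.
DEFAULT_EXCLUSIVE_GENDER_PAIRS: tuple[frozenset[str], ...] = (
    frozenset({"cisgender_male", "cisgender_female"}),
    frozenset({"cisgender_male", "transgender_male"}),
    frozenset({"cisgender_female", "transgender_female"}),
)

#: Sex assigned at birth -> anatomically incompatible cancer sites.
DEFAULT_SEX_SITE_MAP: dict[str, frozenset[str]] = {
    "male": frozenset({"uterine_cervical"}),
    "female": frozenset({"prostate"}),
}

#: Cancer types rare below the young-age cutoff (epidemiologically,
#: overwhelmingly diagnosed past midlife: lung, kidney, bladder, prostate).
DEFAULT_RARE_CANCER_CATALOG: frozenset[str] = frozenset(
    {"lung", "kidney", "bladder", "prostate"}
)


@dataclass(frozen=True)
class RareCancerCatalog:
    types: frozenset[str] = DEFAULT_RARE_CANCER_CATALOG

    def __post_init__(self) -> None:
        unknown = self.types - set(CANCER_TYPE_LEVELS)
        if unknown:
            raise ConfigurationError(f"rare-cancer catalog has unknown types: {sorted(unknown)}")


def _resource_lines(name: str) -> tuple[str, ...]:
    text = (
        importlib.resources.files("surveyscreen.resources").joinpath(name).read_text()
    )
    return tuple(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class Lexicons:
    """Word lists behind the text-based detectors.

    All bundled as plain-text resources and overridable; the off-topic rule
    fires only when IT jargon appears with *no* on-topic (care-related) term.
    """

    it_terms: tuple[str, ...] = ()
    on_topic_terms: tuple[str, ...] = ()
    business_terms: tuple[str, ...] = ()
    given_names_female: tuple[str, ...] = ()
    given_names_male: tuple[str, ...] = ()
    surnames: tuple[str, ...] = ()
    suffix_whitelist: tuple[str, ...] = ("jr", "sr", "ii", "iii", "iv", "md", "phd")
    male_suffixes: tuple[str, ...] = ("jr", "sr", "ii", "iii", "iv")

    @classmethod
    def bundled(cls) -> "Lexicons":
        return cls(
            it_terms=_resource_lines("it_terms.txt"),
            on_topic_terms=_resource_lines("on_topic_terms.txt"),
            business_terms=_resource_lines("business_terms.txt"),
            given_names_female=_resource_lines("given_names_female.txt"),
            given_names_male=_resource_lines("given_names_male.txt"),
            surnames=_resource_lines("surnames.txt"),
        )

    @property
    def given_names(self) -> frozenset[str]:
        return frozenset(self.given_names_female) | frozenset(self.given_names_male)

    def require_name_lists(self) -> None:
        if not self.given_names or not self.surnames:
            raise ConfigurationError(
                "name-based screening requires non-empty given-name and surname lists"
            )


@dataclass(frozen=True)
class ScreenConfig:
    """Complete configuration bundle for the screening pipeline."""

    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    calendar: DisseminationCalendar = field(default_factory=DisseminationCalendar)
    rare_cancers: RareCancerCatalog = field(default_factory=RareCancerCatalog)
    sex_site_map: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_SEX_SITE_MAP)
    )
    exclusive_gender_pairs: tuple[frozenset[str], ...] = DEFAULT_EXCLUSIVE_GENDER_PAIRS
    lexicons: Lexicons | None = None  # None -> bundled lists, loaded lazily
    enable_honeypot_indicator: bool = False
    assume_naive_timestamps_eastern: bool = True
    denominator_policy: str = "all_excluded"  # or "indicator_excluded"

    def resolved_lexicons(self) -> Lexicons:
        return self.lexicons if self.lexicons is not None else Lexicons.bundled()

    def validate(self) -> None:
        if self.denominator_policy not in ("all_excluded", "indicator_excluded"):
            raise ConfigurationError(
                f"unknown denominator_policy {self.denominator_policy!r}"
            )
        for source in SOURCE_LEVELS:
            self.calendar.earliest_date(source)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def thresholds_to_dict(t: ScreeningThresholds) -> dict:
    out = {}
    for f in dc_fields(t):
        v = getattr(t, f.name)
        if isinstance(v, timedelta):
            v = v.total_seconds() / 60.0
        elif isinstance(v, time):
            v = v.isoformat(timespec="minutes")
        out[f.name] = v
    return out


def thresholds_from_dict(d: dict) -> ScreeningThresholds:
    kwargs = dict(d)
    if "burst_max_gap" in kwargs:
        kwargs["burst_max_gap"] = timedelta(minutes=float(kwargs["burst_max_gap"]))
    for key in ("night_window_start", "night_window_end"):
        if key in kwargs and isinstance(kwargs[key], str):
            kwargs[key] = time.fromisoformat(kwargs[key])
    return ScreeningThresholds(**kwargs)


def load_config(path) -> ScreenConfig:
    """Load a ScreenConfig from YAML; absent sections fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "thresholds" in raw:
        kwargs["thresholds"] = thresholds_from_dict(raw["thresholds"])
    if "calendar" in raw:
        earliest = {
            k: (date.fromisoformat(v) if isinstance(v, str) else v)
            for k, v in raw["calendar"].items()
        }
        kwargs["calendar"] = DisseminationCalendar(earliest=earliest)
    if "rare_cancers" in raw:
        kwargs["rare_cancers"] = RareCancerCatalog(types=frozenset(raw["rare_cancers"]))
    if "sex_site_map" in raw:
        kwargs["sex_site_map"] = {
            k: frozenset(v) for k, v in raw["sex_site_map"].items()
        }
    if "exclusive_gender_pairs" in raw:
        kwargs["exclusive_gender_pairs"] = tuple(
            frozenset(p) for p in raw["exclusive_gender_pairs"]
        )
    for key in (
        "enable_honeypot_indicator",
        "assume_naive_timestamps_eastern",
        "denominator_policy",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    cfg = ScreenConfig(**kwargs)
    cfg.validate()
    return cfg


def save_config(cfg: ScreenConfig, path) -> None:
    raw = {
        "thresholds": thresholds_to_dict(cfg.thresholds),
        "calendar": {
            k: (v.isoformat() if v is not None else None)
            for k, v in cfg.calendar.earliest.items()
        },
        "rare_cancers": sorted(cfg.rare_cancers.types),
        "sex_site_map": {k: sorted(v) for k, v in cfg.sex_site_map.items()},
        "exclusive_gender_pairs": [sorted(p) for p in cfg.exclusive_gender_pairs],
        "enable_honeypot_indicator": cfg.enable_honeypot_indicator,
        "assume_naive_timestamps_eastern": cfg.assume_naive_timestamps_eastern,
        "denominator_policy": cfg.denominator_policy,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
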