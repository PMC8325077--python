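"""Full screening cascade: eligibility -> indicator profiling -> elimination.

Stage-1 screening removes ineligible, high-missingness and contradictory
records first; indicator profiling then runs ONLY on stage-1 survivors, and
any survivor with two or more suspicious indicators is eliminated.  The
:class:`FlowCounts` accounting mirrors a flow chart: every input record lands
in exactly one bucket and the buckets sum to the cohort size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .config import ConfigurationError, ScreenConfig
from .eligibility import STAGE_ORDER, EligibilityScreen, EligibilityVerdict
from .indicators import INDICATOR_CODES, HONEYPOT_CODE, IndicatorProfile, IndicatorProfiler
from .io import write_responses
from .schema import QuestionInventory, SurveyResponse

__all__ = [
    "FlowCounts",
    "EliminationDecision",
    "SurveyFraudScreen",
    "run_pipeline",
    "indicator_summary",
    "export_results",
    "format_percentage",
]


@dataclass(frozen=True)
class FlowCounts:
    total: int
    removed_ineligible_core: int
    removed_nonmelanoma: int
    removed_missingness: int
    removed_gender_contradiction: int
    removed_sex_site: int
    removed_indicators: int
    retained: int

    def __post_init__(self) -> None:
        parts = (
            self.removed_ineligible_core,
            self.removed_nonmelanoma,
            self.removed_missingness,
            self.removed_gender_contradiction,
            self.removed_sex_site,
            self.removed_indicators,
            self.retained,
        )
        if any(v < 0 for v in parts) or sum(parts) != self.total:
            raise ValueError(f"flow counts do not conserve the total: {self}")

    @property
    def removed_stage1(self) -> int:
        return (
            self.removed_ineligible_core
            + self.removed_nonmelanoma
            + self.removed_missingness
            + self.removed_gender_contradiction
            + self.removed_sex_site
        )

    @property
    def removed_total(self) -> int:
        return self.removed_stage1 + self.removed_indicators


@dataclass(frozen=True)
class EliminationDecision:
    """Exactly one outcome per respondent."""

    respondent_id: str
    outcome: str  # "retained" | "removed_indicators" | one of STAGE_ORDER
    stage1_reasons: frozenset[str] = frozenset()
    fired_indicators: frozenset[str] = frozenset()  # empty if never profiled

    @property
    def retained(self) -> bool:
        return self.outcome == "retained"

    @property
    def excluded(self) -> bool:
        return not self.retained


_STAGE_TO_FLOW_FIELD = {
    "ineligible_core": "removed_ineligible_core",
    "nonmelanoma_only": "removed_nonmelanoma",
    "excess_missingness": "removed_missingness",
    "discordant_gender": "removed_gender_contradiction",
    "discordant_sex_site": "removed_sex_site",
}


class SurveyFraudScreen(BaseEstimator):
    """End-to-end fraud screen as a scikit-learn-style estimator.

    ``fit(X)`` runs the cascade on a cohort (sequence of
    :class:`SurveyResponse`) and exposes:

    - :attr:`decisions_` — one :class:`EliminationDecision` per record,
    - :attr:`flow_counts_` — the flow-chart accounting,
    - :attr:`indicator_marginals_` — per-indicator counts among the profiled
      stage-1 survivors that were eliminated,
    - :attr:`labels_` — "retained"/"excluded" per record (input order).

    ``fit_predict(X)`` returns :attr:`labels_`.  The rules carry no learned
    state, so ``predict`` on a new cohort simply re-runs the cascade.
    """

    def __init__(self, config: ScreenConfig | None = None,
                 inventory: QuestionInventory | None = None):
        self.config = config
        self.inventory = inventory

    # -- internals ----------------------------------------------------------

    def _components(self):
        cfg = self.config or ScreenConfig()
        cfg.validate()
        inv = self.inventory or QuestionInventory()
        eligibility = EligibilityScreen(
            thresholds=cfg.thresholds,
            inventory=inv,
            exclusive_gender_pairs=cfg.exclusive_gender_pairs,
            sex_site_map=cfg.sex_site_map,
        )
        profiler = IndicatorProfiler(
            thresholds=cfg.thresholds,
            calendar=cfg.calendar,
            catalog=cfg.rare_cancers,
            lexicons=cfg.resolved_lexicons(),
            enable_honeypot=cfg.enable_honeypot_indicator,
        )
        return cfg, eligibility, profiler

    def fit(self, X: Sequence[SurveyResponse], y=None) -> "SurveyFraudScreen":
        cfg, eligibility, profiler = self._components()
        ids = [rec.respondent_id for rec in X]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("respondent ids are not unique within the cohort")

        eligibility.fit(X)
        verdicts: list[EligibilityVerdict] = eligibility.verdicts_
        survivors = [rec for rec, v in zip(X, verdicts) if v.removal_stage is None]

        profiler.fit(survivors)
        profile_by_id: dict[str, IndicatorProfile] = {
            p.respondent_id: p for p in profiler.profiles_
        }

        cutoff = cfg.thresholds.indicator_elimination_count
        decisions: list[EliminationDecision] = []
        for rec, verdict in zip(X, verdicts):
            if verdict.removal_stage is not None:
                decisions.append(
                    EliminationDecision(
                        respondent_id=rec.respondent_id,
                        outcome=verdict.removal_stage,
                        stage1_reasons=verdict.reasons,
                    )
                )
                continue
            profile = profile_by_id[rec.respondent_id]
            outcome = "removed_indicators" if profile.count >= cutoff else "retained"
            decisions.append(
                EliminationDecision(
                    respondent_id=rec.respondent_id,
                    outcome=outcome,
                    fired_indicators=profile.fired,
                )
            )

        stage_counts = eligibility.stage_counts_
        n_indicator_removed = sum(d.outcome == "removed_indicators" for d in decisions)
        self.flow_counts_ = FlowCounts(
            total=len(list(X)),
            removed_ineligible_core=stage_counts["ineligible_core"],
            removed_nonmelanoma=stage_counts["nonmelanoma_only"],
            removed_missingness=stage_counts["excess_missingness"],
            removed_gender_contradiction=stage_counts["discordant_gender"],
            removed_sex_site=stage_counts["discordant_sex_site"],
            removed_indicators=n_indicator_removed,
            retained=sum(d.retained for d in decisions),
        )
        self.decisions_ = decisions
        self.profiles_ = profiler.profiles_
        codes = INDICATOR_CODES + (
            (HONEYPOT_CODE,) if cfg.enable_honeypot_indicator else ()
        )
        eliminated = [d for d in decisions if d.outcome == "removed_indicators"]
        self.indicator_marginals_ = {
            code: sum(code in d.fired_indicators for d in eliminated) for code in codes
        }
        self.labels_ = ["retained" if d.retained else "excluded" for d in decisions]
        return self

    def fit_predict(self, X: Sequence[SurveyResponse], y=None) -> list[str]:
        return self.fit(X).labels_

    def predict(self, X: Sequence[SurveyResponse]) -> list[str]:
        """Stateless re-application of the cascade to a cohort."""
        return type(self)(config=self.config, inventory=self.inventory).fit_predict(X)


def run_pipeline(
    cohort: Sequence[SurveyResponse],
    config: ScreenConfig | None = None,
    inventory: QuestionInventory | None = None,
) -> tuple[list[EliminationDecision], FlowCounts, dict[str, int]]:
    """Run the cascade; returns decisions, flow counts, indicator marginals."""
    screen = SurveyFraudScreen(config=config, inventory=inventory).fit(cohort)
    return screen.decisions_, screen.flow_counts_, screen.indicator_marginals_


# ---------------------------------------------------------------------------
# Summaries and export
# ---------------------------------------------------------------------------

def format_percentage(numerator: int, denominator: int) -> str:
    """Half-up to 1 decimal; a trailing ``.0`` prints as an integer
    (58.2 -> "58.2", 70.0 -> "70")."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return str(q.to_integral_value()) if q == q.to_integral_value() else str(q)


def indicator_summary(
    decisions: Sequence[EliminationDecision],
    denominator_policy: str = "all_excluded",
    enable_honeypot: bool = False,
) -> pd.DataFrame:
    """Per-indicator counts and percentages among eliminated responses.

    Indicators overlap, so counts do not sum to the number eliminated.  The
    percentage denominator is, by default, ALL excluded responses (stage-1
    removals included); ``denominator_policy="indicator_excluded"`` restricts
    it to indicator-based eliminations only.
    """
    excluded = [d for d in decisions if d.excluded]
    eliminated = [d for d in decisions if d.outcome == "removed_indicators"]
    if denominator_policy == "all_excluded":
        denom = len(excluded)
    elif denominator_policy == "indicator_excluded":
        denom = len(eliminated)
    else:
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    if denom == 0:
        raise ValueError("no excluded responses: indicator summary denominator is zero")

    codes = INDICATOR_CODES + ((HONEYPOT_CODE,) if enable_honeypot else ())
    rows = []
    for code in codes:
        n = sum(code in d.fired_indicators for d in eliminated)
        rows.append(
            {
                "indicator": code,
                "count": n,
                "percentage": float(n * 100 / denom),
                "printed": f"{n} ({format_percentage(n, denom)})",
            }
        )
    return pd.DataFrame(rows)


def export_results(
    decisions: Sequence[EliminationDecision],
    cohort: Sequence[SurveyResponse],
    outdir: str | Path,
    flow_counts: FlowCounts | None = None,
) -> dict[str, Path]:
    """Write retained.csv / excluded.csv (exact partition), flowchart.json
    and a machine-readable audit log of per-record outcomes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {d.respondent_id: d for d in decisions}
    if set(by_id) != {rec.respondent_id for rec in cohort}:
        raise ValueError("decisions and cohort do not cover the same respondent ids")

    retained = [rec for rec in cohort if by_id[rec.respondent_id].retained]
    excluded = [rec for rec in cohort if by_id[rec.respondent_id].excluded]
    paths = {
        "retained": outdir / "retained.csv",
        "excluded": outdir / "excluded.csv",
        "flowchart": outdir / "flowchart.json",
        "audit": outdir / "audit.jsonl",
    }
    write_responses(retained, paths["retained"])
    write_responses(excluded, paths["excluded"])

    if flow_counts is None:
        stage_field = dict(_STAGE_TO_FLOW_FIELD)
        counts = {f: 0 for f in stage_field.values()}
        for d in decisions:
            if d.outcome in stage_field:
                counts[stage_field[d.outcome]] += 1
        flow_counts = FlowCounts(
            total=len(list(cohort)),
            removed_indicators=sum(d.outcome == "removed_indicators" for d in decisions),
            retained=len(retained),
            **counts,
        )
    paths["flowchart"].write_text(json.dumps(asdict(flow_counts), indent=2) + "\n")

    with paths["audit"].open("w") as fh:
        for d in decisions:
            fh.write(
                json.dumps(
                    {
                        "respondent_id": d.respondent_id,
                        "outcome": d.outcome,
                        "stage1_reasons": sorted(d.stage1_reasons),
                        "fired_indicators": sorted(d.fired_indicators),
                    }
                )
                + "\n"
            )
    return paths
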