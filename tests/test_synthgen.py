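"""Synthetic-cohort generator: determinism, planting fidelity, evaluation."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from surveyscreen import (
    EASTERN,
    ConfigurationError,
    GeneratorConfig,
    evaluate_detection,
    generate_cohort,
    plant_burst,
    run_pipeline,
    write_responses,
)
from surveyscreen.indicators import flag_suspicious_timing
from surveyscreen.schema import SurveyResponse

from conftest import small_config


class TestPlantBurst:
    def test_arithmetic_sequence(self):
        base = datetime(2020, 10, 10, 10, 0, tzinfo=EASTERN)
        ts = plant_burst(base, 3, timedelta(minutes=2))
        assert ts == [base, base + timedelta(minutes=2), base + timedelta(minutes=4)]

    def test_ten_at_four_minutes_fires_the_burst_rule(self):
        base = datetime(2020, 10, 10, 10, 0, tzinfo=EASTERN)
        cohort = [
            SurveyResponse(respondent_id=f"b{i}", submission_timestamp=t)
            for i, t in enumerate(plant_burst(base, 10, timedelta(minutes=4)))
        ]
        assert flag_suspicious_timing(cohort) == {r.respondent_id for r in cohort}

    def test_ten_at_six_minutes_does_not(self):
        base = datetime(2020, 10, 10, 10, 0, tzinfo=EASTERN)
        cohort = [
            SurveyResponse(respondent_id=f"b{i}", submission_timestamp=t)
            for i, t in enumerate(plant_burst(base, 10, timedelta(minutes=6)))
        ]
        assert flag_suspicious_timing(cohort) == set()

    def test_size_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            plant_burst(datetime(2020, 10, 10, tzinfo=EASTERN), 0, timedelta(minutes=1))


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        a, _ = generate_cohort(small_config(seed=21))
        b, _ = generate_cohort(small_config(seed=21))
        write_responses(a, tmp_path / "a.csv")
        write_responses(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_different_cohort(self):
        a, _ = generate_cohort(small_config(seed=21))
        b, _ = generate_cohort(small_config(seed=22))
        assert a != b

    def test_bundled_study_scale_yaml_matches_defaults(self):
        import importlib.resources

        from surveyscreen import load_generator_config, paper_scale_config

        path = importlib.resources.files("surveyscreen.resources").joinpath(
            "paper_scale.yaml"
        )
        assert load_generator_config(str(path)) == paper_scale_config(seed=0)


class TestPlantingFidelity:
    def test_all_legit_config_fully_retained(self):
        cfg = GeneratorConfig(
            seed=5, n_legit=50, n_fraud=0,
            stage1_counts={}, indicator_counts={},
        )
        records, truth = generate_cohort(cfg)
        assert len(records) == 50
        _, fc, _ = run_pipeline(records)
        assert fc.retained == 50

    def test_single_fraud_record_with_two_indicators_excluded(self):
        cfg = GeneratorConfig(
            seed=5, n_legit=20, n_fraud=1, stage1_counts={},
            indicator_counts={"AGE_DISCORD": 1, "SUSPICIOUS_EMAIL_ADDRESS": 1},
        )
        records, truth = generate_cohort(cfg)
        decisions, fc, _ = run_pipeline(records)
        assert fc.retained == 20 and fc.removed_indicators == 1
        report = evaluate_detection(decisions, truth)
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_indicator_marginals_hit_exactly(self, small_cohort):
        records, truth = small_cohort
        cfg = small_config()
        planted = list(truth.planted_indicators.values())
        for code, want in cfg.indicator_counts.items():
            assert sum(code in s for s in planted) == want
        assert all(len(s) >= 2 for s in planted)

    def test_stage1_reasons_planted_disjointly(self, small_cohort):
        records, truth = small_cohort
        decisions, _, _ = run_pipeline(records)
        by_id = {d.respondent_id: d for d in decisions}
        stage_map = {
            "non_us_resident": "ineligible_core",
            "stage_0": "ineligible_core",
            "no_cancer_diagnosis": "ineligible_core",
            "nonmelanoma_only": "nonmelanoma_only",
            "excess_missingness": "excess_missingness",
            "discordant_gender": "discordant_gender",
            "discordant_sex_site": "discordant_sex_site",
        }
        for rid, reason in truth.stage1_reason.items():
            assert by_id[rid].outcome == stage_map[reason]

    def test_age_profiles_recovered_within_two_se(self, paper_cohort):
        records, truth = paper_cohort
        cfg = GeneratorConfig()
        for clazz, mean, sd in (
            ("legit", cfg.legit_age_mean, cfg.legit_age_sd),
            ("fraud", cfg.fraud_age_mean, cfg.fraud_age_sd),
        ):
            ages = [
                r.reported_age
                for r in records
                if truth.clazz[r.respondent_id] == clazz and r.reported_age is not None
            ]
            se = sd / np.sqrt(len(ages))
            assert abs(np.mean(ages) - mean) < 2 * se


class TestConfigValidation:
    def test_indicator_count_exceeding_n_fraud(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(
                n_fraud=5, indicator_counts={"AGE_DISCORD": 6, "SUSPICIOUS_NAME": 5}
            ).validate()

    def test_counts_too_small_for_two_per_record(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(
                n_fraud=5, indicator_counts={"AGE_DISCORD": 5, "SUSPICIOUS_NAME": 4}
            ).validate()

    def test_lonely_duplicate_email_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(
                n_fraud=1, indicator_counts={"DUP_EMAIL": 1, "AGE_DISCORD": 1}
            ).validate()

    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(indicator_probability=1.5).validate()


class TestEvaluateDetection:
    def test_perfect_planting_scores_one(self, small_cohort):
        records, truth = small_cohort
        decisions, _, _ = run_pipeline(records)
        report = evaluate_detection(decisions, truth)
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0
        for code, cm in report.per_indicator.items():
            assert cm["fp"] == 0 and cm["fn"] == 0

    def test_single_indicator_fraud_is_never_eliminated(self):
        cfg = GeneratorConfig(
            seed=6, n_legit=10, n_fraud=15, stage1_counts={},
            indicator_probability=1.0, probabilistic_indicators=("AGE_DISCORD",),
        )
        records, truth = generate_cohort(cfg)
        decisions, _, _ = run_pipeline(records)
        report = evaluate_detection(decisions, truth)
        assert report.sensitivity == 0.0
        assert report.specificity == 1.0

    def test_id_mismatch_rejected(self, small_cohort):
        records, truth = small_cohort
        decisions, _, _ = run_pipeline(records)
        with pytest.raises(ValueError):
            evaluate_detection(decisions[:-1], truth)
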