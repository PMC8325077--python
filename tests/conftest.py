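import pytest

from surveyscreen import (
    GeneratorConfig,
    SurveyFraudScreen,
    generate_cohort,
    paper_scale_config,
)


def small_config(seed: int = 11, **overrides) -> GeneratorConfig:
    """A quick-to-generate cohort exercising every planting path."""
    kwargs = dict(
        seed=seed,
        n_legit=40,
        n_fraud=30,
        stage1_counts={
            "non_us_resident": 2,
            "stage_0": 2,
            "no_cancer_diagnosis": 2,
            "nonmelanoma_only": 3,
            "excess_missingness": 4,
            "discordant_gender": 2,
            "discordant_sex_site": 2,
        },
        indicator_counts={
            "AGE_DISCORD": 10,
            "RARE_CANCER_YOUNG": 8,
            "SOURCE_INCONGRUENT": 18,
            "OFFTOPIC_TEXT": 3,
            "DUP_TELEHEALTH": 4,
            "DUP_SUGGESTION": 5,
            "DUP_EMAIL": 4,
            "TIMELINE_DX_LT2_TX_2TO5": 2,
            "TIMELINE_DX_LE5_TX_GT5": 3,
            "SUSPICIOUS_TIMING": 22,
            "SUSPICIOUS_EMAIL_ADDRESS": 6,
            "SUSPICIOUS_NAME": 5,
        },
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def paper_cohort():
    """Study-scale synthetic cohort (1977 records) plus planted truth."""
    return generate_cohort(paper_scale_config(seed=20201008))


@pytest.fixture(scope="session")
def paper_screen(paper_cohort):
    records, _ = paper_cohort
    return SurveyFraudScreen().fit(records)
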