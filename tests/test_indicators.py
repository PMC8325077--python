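"""The twelve suspicious-response detectors."""

from datetime import date, datetime, timedelta

import pytest

from surveyscreen import (
    EASTERN,
    ConfigurationError,
    Lexicons,
    ScreeningThresholds,
    SurveyResponse,
    profile_cohort,
)
from surveyscreen.indicators import (
    flag_age_discordance,
    flag_duplicate_email,
    flag_duplicate_text,
    flag_offtopic_text,
    flag_rare_cancer_young,
    flag_source_incongruence,
    flag_suspicious_email_address,
    flag_suspicious_name,
    flag_suspicious_timing,
    flag_timeline_inconsistency,
)


def _rec(rid="r", **kw):
    defaults = dict(
        respondent_id=rid,
        submission_timestamp=datetime(2020, 10, 10, 14, 0, tzinfo=EASTERN),
    )
    defaults.update(kw)
    return SurveyResponse(**defaults)


class TestAgeDiscordance:
    def test_birth_year_equal_to_survey_year(self):
        assert flag_age_discordance(_rec(date_of_birth=date(2020, 1, 1)))

    def test_consistent_age_passes(self):
        rec = _rec(reported_age=45, date_of_birth=date(1975, 6, 1))
        assert not flag_age_discordance(rec)

    def test_large_discrepancy_fires(self):
        rec = _rec(reported_age=30, date_of_birth=date(1960, 1, 1))
        assert flag_age_discordance(rec)

    def test_exactly_one_year_off_is_tolerated(self):
        # calculated age 44 (birthday not yet passed) vs reported 45
        rec = _rec(reported_age=45, date_of_birth=date(1975, 12, 1))
        assert not flag_age_discordance(rec)

    def test_missing_dob_or_age_never_fires(self):
        assert not flag_age_discordance(_rec(reported_age=30))
        assert not flag_age_discordance(_rec(date_of_birth=date(1960, 1, 1)))


class TestRareCancerYoung:
    @pytest.mark.parametrize(
        "age, types, expected",
        [(35, {"lung"}, True), (45, {"lung"}, False), (35, {"breast"}, False),
         (39, {"kidney", "breast"}, True), (None, {"lung"}, False)],
    )
    def test_rule(self, age, types, expected):
        assert flag_rare_cancer_young(_rec(reported_age=age, cancer_types=types)) is expected


class TestSourceIncongruence:
    def test_claim_before_dissemination_fires(self):
        rec = _rec(
            survey_source="coc_email",
            submission_timestamp=datetime(2020, 10, 9, 10, 0, tzinfo=EASTERN),
        )
        assert flag_source_incongruence(rec)

    def test_claim_after_dissemination_passes(self):
        rec = _rec(
            survey_source="community_partner",
            submission_timestamp=datetime(2020, 10, 9, 10, 0, tzinfo=EASTERN),
        )
        assert not flag_source_incongruence(rec)

    def test_unknown_source_never_fires(self):
        rec = _rec(
            survey_source="other",
            submission_timestamp=datetime(2020, 10, 1, 10, 0, tzinfo=EASTERN),
        )
        assert not flag_source_incongruence(rec)

    def test_utc_timestamp_compared_in_eastern(self):
        # 02:00 UTC Oct 13 is still Oct 12 Eastern -> before the email blast
        from zoneinfo import ZoneInfo

        rec = _rec(
            survey_source="coc_email",
            submission_timestamp=datetime(2020, 10, 13, 2, 0, tzinfo=ZoneInfo("UTC")),
        )
        assert flag_source_incongruence(rec)


class TestOfftopicText:
    def test_it_jargon_fires(self):
        rec = _rec(telehealth_comment="great software, nice user interface and network")
        assert flag_offtopic_text(rec)

    def test_care_related_text_passes(self):
        assert not flag_offtopic_text(_rec(telehealth_comment="my oncologist was kind over video"))

    def test_empty_text_passes(self):
        assert not flag_offtopic_text(_rec())

    def test_on_topic_term_vetoes(self):
        rec = _rec(telehealth_comment="the software my doctor used worked")
        assert not flag_offtopic_text(rec)


class TestDuplicates:
    def test_identical_long_comments_both_flagged(self):
        text = "the video call dropped twice but we finished the visit"
        cohort = [_rec("a", telehealth_comment=text), _rec("b", telehealth_comment=text)]
        assert flag_duplicate_text(cohort, "telehealth_comment") == {"a", "b"}

    def test_unique_comments_none_flagged(self):
        cohort = [_rec("a", telehealth_comment="first unique long comment here"),
                  _rec("b", telehealth_comment="second unique long comment here")]
        assert flag_duplicate_text(cohort, "telehealth_comment") == set()

    def test_matches_brute_force_pairwise_oracle(self):
        shared = "three of us typed exactly this same sentence"
        cohort = [
            _rec("a", final_suggestion=shared),
            _rec("b", final_suggestion=shared),
            _rec("c", final_suggestion=shared),
            _rec("d", final_suggestion="a different and unique suggestion"),
        ]

        def normalize(s):
            import re
            return re.sub(r"\s+", " ", re.sub(r"[^\w\s]", " ", s.lower())).strip()

        oracle = {
            x.respondent_id
            for x in cohort
            for y in cohort
            if x.respondent_id != y.respondent_id
            and len(normalize(x.final_suggestion)) >= 15
            and normalize(x.final_suggestion) == normalize(y.final_suggestion)
        }
        assert flag_duplicate_text(cohort, "final_suggestion") == oracle == {"a", "b", "c"}

    def test_short_texts_never_flag(self):
        cohort = [_rec("a", telehealth_comment="n/a"), _rec("b", telehealth_comment="n/a")]
        assert flag_duplicate_text(cohort, "telehealth_comment") == set()

    def test_normalization_ignores_case_punctuation_whitespace(self):
        cohort = [
            _rec("a", telehealth_comment="Worked  GREAT, no problems at all!"),
            _rec("b", telehealth_comment="worked great no problems at all"),
        ]
        assert flag_duplicate_text(cohort, "telehealth_comment") == {"a", "b"}

    def test_duplicate_email_case_insensitive(self):
        cohort = [_rec("a", email="A@x.com"), _rec("b", email="a@x.com")]
        assert flag_duplicate_email(cohort) == {"a", "b"}

    def test_distinct_and_empty_emails_never_flag(self):
        cohort = [_rec("a", email="a@x.com"), _rec("b", email="b@x.com"),
                  _rec("c", email=""), _rec("d", email="")]
        assert flag_duplicate_email(cohort) == set()


class TestTimeline:
    @pytest.mark.parametrize(
        "dx, tx, expected",
        [
            ("<2", "2-5", {"TIMELINE_DX_LT2_TX_2TO5"}),
            ("2-5", ">5", {"TIMELINE_DX_LE5_TX_GT5"}),
            ("<2", ">5", {"TIMELINE_DX_LE5_TX_GT5"}),
            (">5", ">5", set()),
            ("<2", "<2", set()),
            (None, "2-5", set()),
        ],
    )
    def test_rule(self, dx, tx, expected):
        rec = _rec(time_since_diagnosis=dx, time_since_treatment=tx)
        assert flag_timeline_inconsistency(rec) == expected


class TestSuspiciousTiming:
    def _runs(self, n, gap_minutes, start_hour=10):
        base = datetime(2020, 10, 10, start_hour, 0, tzinfo=EASTERN)
        return [
            _rec(f"t{i}", submission_timestamp=base + i * timedelta(minutes=gap_minutes))
            for i in range(n)
        ]

    def test_twelve_at_two_minute_gaps_all_flagged(self):
        cohort = self._runs(12, 2)
        assert flag_suspicious_timing(cohort) == {r.respondent_id for r in cohort}

    def test_nine_in_a_run_is_below_threshold(self):
        assert flag_suspicious_timing(self._runs(9, 1)) == set()

    def test_gap_above_five_minutes_breaks_the_run(self):
        assert flag_suspicious_timing(self._runs(12, 6)) == set()

    def test_night_submission_flagged_alone(self):
        rec = _rec("n", submission_timestamp=datetime(2020, 10, 10, 2, 30, tzinfo=EASTERN))
        assert flag_suspicious_timing([rec]) == {"n"}

    def test_four_am_is_outside_the_night_window(self):
        rec = _rec("n", submission_timestamp=datetime(2020, 10, 10, 4, 0, tzinfo=EASTERN))
        assert flag_suspicious_timing([rec]) == set()

    def test_lowering_burst_min_run_is_monotone(self):
        cohort = self._runs(9, 2) + self._runs(4, 3, start_hour=15)
        flagged_by_run = {}
        for min_run in (12, 9, 4, 2):
            t = ScreeningThresholds(burst_min_run=min_run)
            flagged_by_run[min_run] = flag_suspicious_timing(cohort, t)
        assert flagged_by_run[12] <= flagged_by_run[9] <= flagged_by_run[4] <= flagged_by_run[2]

    def test_permutation_invariant(self):
        cohort = self._runs(12, 2)
        assert flag_suspicious_timing(cohort[::-1]) == flag_suspicious_timing(cohort)


class TestSuspiciousEmailAddress:
    @pytest.mark.parametrize(
        "email, address, expected",
        [
            ("xk29fj38dk2a@mail.com", "", True),           # 12-char mixed run
            ("", '12 Oak St "Springfield" IL', True),      # quotation marks
            ("jane.doe@gmail.com", "12 Oak St, Springfield, IL 62704", False),
            ("", "12 Oak", True),                          # incomplete address
            ("", "1 Main St Warehouse Outlet Mall", True), # business lexicon
            ("weird..dots@mail.com", "", True),
            ("", "", False),
        ],
    )
    def test_rule(self, email, address, expected):
        rec = _rec(email=email, postal_address=address)
        assert flag_suspicious_email_address(rec) is expected

    def test_long_natural_word_run_is_not_random(self):
        # all-letter run with vowels in every window
        assert not flag_suspicious_email_address(_rec(email="telemedicinelover@mail.com"))


class TestSuspiciousName:
    def test_flipped_first_and_last(self):
        assert flag_suspicious_name(_rec(first_name="Smith", last_name="John"))

    def test_digits_in_suffix(self):
        assert flag_suspicious_name(
            _rec(first_name="Maria", last_name="Lopez", name_suffix="Jr4")
        )

    def test_clean_name_passes(self):
        assert not flag_suspicious_name(_rec(first_name="Maria", last_name="Lopez"))

    def test_name_part_crossover(self):
        assert flag_suspicious_name(_rec(first_name="Gar", last_name="Garcia"))

    def test_male_suffix_with_female_name(self):
        assert flag_suspicious_name(
            _rec(first_name="Mary", last_name="Jones", name_suffix="Jr")
        )

    def test_male_suffix_with_male_name_passes(self):
        assert not flag_suspicious_name(
            _rec(first_name="John", last_name="Jones", name_suffix="Jr")
        )

    def test_missing_name_lists_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            flag_suspicious_name(_rec(first_name="A", last_name="B"), lexicons=Lexicons())


class TestProfiler:
    def test_counts_union_of_fired_detectors(self):
        rec = _rec(
            "p1",
            date_of_birth=date(2020, 2, 2),
            submission_timestamp=datetime(2020, 10, 10, 2, 30, tzinfo=EASTERN),
            survey_source="community_partner",
        )
        profile = profile_cohort([rec])[0]
        assert profile.fired == {"AGE_DISCORD", "SUSPICIOUS_TIMING"}
        assert profile.count == 2

    def test_clean_record_scores_zero(self, small_cohort):
        records, truth = small_cohort
        clean = [r for r in records if truth.clazz[r.respondent_id] == "legit"]
        assert all(p.count == 0 for p in profile_cohort(clean))

    def test_planted_truth_recovered_record_for_record(self, small_cohort):
        records, truth = small_cohort
        survivors = [
            r for r in records if truth.clazz[r.respondent_id] != "ineligible"
        ]
        by_id = {p.respondent_id: p for p in profile_cohort(survivors)}
        for rid, planted in truth.planted_indicators.items():
            assert by_id[rid].fired == planted
        for rid, clazz in truth.clazz.items():
            if clazz == "legit":
                assert by_id[rid].fired == frozenset()

    def test_cohort_permutation_cannot_change_profiles(self, small_cohort):
        records, truth = small_cohort
        survivors = [r for r in records if truth.clazz[r.respondent_id] != "ineligible"]
        fwd = {p.respondent_id: p for p in profile_cohort(survivors)}
        rev = {p.respondent_id: p for p in profile_cohort(survivors[::-1])}
        assert fwd == rev
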