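# surveyscreen

Rule-based fraud screening for incentivized web-survey cohorts.

Web surveys that offer a financial incentive and circulate on social media
attract bots and opportunistic responders; in health-survey settings a
majority of submissions can be fraudulent, and a CAPTCHA alone does not stop
them. `surveyscreen` implements a transparent, fully configurable screening
cascade for wide one-row-per-respondent exports (REDCap-style CSV), designed
around a cancer-survivor survey but reusable for any cohort with
demographics, identity fields, timestamps and open text:

1. **Eligibility screen** — remove respondents who are ineligible (non-US
   residence, stage 0 disease, no cancer diagnosis, only nonmelanoma skin
   cancer), who leave ≥35% of substantive questions unanswered, or whose
   answers contradict themselves (mutually exclusive gender selections;
   sex assigned at birth incompatible with the anatomic site of the reported
   cancer). Each record is attributed to the *first* stage it fails, so stage
   counts are disjoint and conserve the total.
2. **Suspicious-indicator profiling** — twelve independent detectors run on
   the stage-1 survivors: reported-vs-calculated age discordance; a cancer
   type rare under age 40; a claimed recruitment source that predates that
   source's dissemination date; off-topic (IT-jargon) open text; duplicated
   telehealth comments, final suggestions, or email addresses; two
   diagnosis/treatment timeline contradictions; suspicious submission timing
   (runs of ≥10 submissions each within 5 minutes of the next, or any
   submission between midnight and 4 AM US Eastern); random-looking or
   malformed email/postal identities; and implausible name/suffix patterns.
3. **Elimination rule** — any survivor with **two or more** indicators is
   removed. Flow-chart accounting, per-indicator summaries, a retained vs
   excluded demographic comparison (chi-square / Fisher exact / Welch t), and
   machine-readable audit logs come out the other end.

Because real screening data cannot be shared, the package includes a
synthetic-cohort generator that plants each rule pattern *exactly* —
per-indicator marginal totals, burst timestamps, duplicate groups,
pre-dissemination sources — together with ground truth, so the whole cascade
is testable end to end (exact recovery: sensitivity = specificity = 1 on
noiseless plantings).

## Worked example

```python
from surveyscreen import (
    SurveyFraudScreen, evaluate_detection, generate_cohort,
    indicator_summary, paper_scale_config,
)

records, truth = generate_cohort(paper_scale_config(seed=7))
screen = SurveyFraudScreen().fit(records)
fc = screen.flow_counts_
print(f"total={fc.total} stage1={fc.removed_stage1} "
      f"indicators={fc.removed_indicators} retained={fc.retained}")
print(indicator_summary(screen.decisions_)[["indicator", "printed"]]
      .to_string(index=False))
rep = evaluate_detection(screen.decisions_, truth)
print("sensitivity", rep.sensitivity, "specificity", rep.specificity)
```

prints

```
total=1977 stage1=327 indicators=1081 retained=569
               indicator    printed
             AGE_DISCORD 250 (17.8)
       RARE_CANCER_YOUNG 283 (20.1)
      SOURCE_INCONGRUENT 820 (58.2)
           OFFTOPIC_TEXT     56 (4)
          DUP_TELEHEALTH   34 (2.4)
          DUP_SUGGESTION  107 (7.6)
               DUP_EMAIL   20 (1.4)
 TIMELINE_DX_LT2_TX_2TO5   11 (0.8)
  TIMELINE_DX_LE5_TX_GT5     57 (4)
       SUSPICIOUS_TIMING   986 (70)
SUSPICIOUS_EMAIL_ADDRESS 166 (11.8)
         SUSPICIOUS_NAME   78 (5.5)
sensitivity 1.0 specificity 1.0
```

Of 1977 synthetic responses, 327 fall at stage 1, 1081 are eliminated on the
≥2-indicator rule, and 569 are retained. The `printed` column gives each
indicator's count among eliminated records with its percentage of **all**
1408 excluded responses (indicators overlap, so counts exceed 1081); e.g.
820 records (58.2%) claimed a recruitment source before that source had been
used. Sensitivity/specificity of 1.0 confirm the pipeline recovered the
planted fraud/legitimate labels exactly.

The same operations are available from the shell:

```bash
surveyscreen simulate --seed 7 --outdir sim/         # cohort.csv + truth.csv
surveyscreen run --input sim/cohort.csv --outdir out/  # retained/excluded/audit
surveyscreen summarize --input sim/cohort.csv
surveyscreen compare --input sim/cohort.csv --out table2.csv
```

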