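# Methods

## The screening model

`surveyscreen` treats fraud detection in incentivized web surveys as a
deterministic, rule-based classification problem. No model is trained: every
decision is a pure function of one respondent's record plus configuration,
except for three cohort-level detectors (duplicate text, duplicate email,
submission timing) that are permutation-invariant functions of the whole
cohort. This choice favours auditability — every exclusion carries a
machine-readable list of the exact rules it tripped — over statistical
subtlety, which matches how survey teams actually adjudicate fraud and makes
decisions defensible to an IRB or a journal.

The cascade has two stages.

**Stage 1 — eligibility and internal consistency.** Records are removed, in
order, for: core ineligibility (living outside the US, stage 0 disease, or
an explicit "no cancer diagnosis"); only nonmelanoma skin cancer; missing
answers on ≥35% of substantive questions; a mutually exclusive
gender-identity pair (e.g. cisgender male *and* cisgender female; same-axis
cis/trans pairs are also included by default); and a cancer site
anatomically impossible for the reported sex at birth (male ↔
uterine/cervical, female ↔ prostate, configurable map). A record failing
several rules is counted at the *first* failed stage, so the per-stage
removal counts are disjoint and sum to the total removed — the property a
flow chart needs.

**Stage 2 — suspicious indicators.** Twelve detectors run on stage-1
survivors only (profiling the already-removed records would let their
duplicates and timestamps contaminate the cohort-level rules). A survivor
with ≥2 indicators is eliminated. One indicator alone is deliberately not
disqualifying: each rule has benign explanations (a typo in age, a genuine
night-shift worker), and requiring two independent irregularities is what
keeps the false-positive rate acceptable.

## Parameters that matter

All constants live in `ScreeningThresholds` (YAML-overridable):

| parameter | default | meaning |
|---|---|---|
| `missingness_cutoff` | 0.35 | fraction of the question inventory unanswered |
| `indicator_elimination_count` | 2 | indicators needed to eliminate |
| `age_discordance_years` | 1 | tolerated \|reported − DOB-calculated\| age gap (years) |
| `young_age_cutoff` | 40 | "young" bound for the rare-cancer rule (years) |
| `burst_min_run` | 10 | run length that marks scripted submission |
| `burst_max_gap` | 5 min | max successive gap inside a run |
| `night_window` | 00:00–04:00 | Eastern clock window flagged per se |
| `random_run_min_length` | 10 | alphanumeric run length scored for randomness |
| `duplicate_text_min_length` | 15 chars | shorter normalized texts never count as duplicates |
| `address_min_tokens` | 4 | fewer tokens ⇒ "incomplete address" |

Notable interpretation choices (each configurable):

- **Question inventory.** The 35% rule needs a denominator. We count the 24
  substantive items (demographics, cancer history, open text, source) and
  exclude identity/incentive fields and the bot traps; declining to identify
  oneself is not "missing data" in the survey sense. "Prefer not to answer"
  is an answer, not a missing value.
- **Burst rule.** "At least 10 in succession within 5 minutes of each other"
  is read as *chained* gaps: maximal runs, in timestamp order, where every
  successive gap is ≤5 minutes; every member of a run of length ≥10 is
  flagged. The alternative any-10-inside-5-minutes window reading is far
  stricter and does not match the phenomenon (scripted submission at a
  steady cadence). All clock comparisons happen in US Eastern time; naive
  timestamps are assumed Eastern by a config flag.
- **Randomness scoring for email local parts.** A ≥10-character alphanumeric
  run is "random" if it mixes digits and letters, or is all-consonant in
  some 5-character window; this reproduces the keyboard-mash pattern class
  without a trained model. Strange punctuation/capitalisation is a small
  regex set (consecutive dots, aLtErNaTiNg case, quoting characters).
- **Address checks.** Business-address and not-a-real-address cannot be
  decided offline; we approximate with a business-keyword lexicon and
  structural checks (token count, quotation marks, internal-caps/spacing
  anomalies) and document that geocoding is out of scope.
- **Off-topic text.** A record is off-topic only if an open-text field hits
  the IT-jargon lexicon *and* contains no care-related term; the veto list
  keeps "the software my doctor used" from flagging.
- **Name heuristics.** Bundled few-hundred-entry frequency-ranked given-name
  and surname lists (user-replaceable) drive the flipped-name and
  gendered-suffix rules; a digit or non-whitelisted token in the suffix field
  flags unconditionally.
- **No-diagnosis rule.** Fires only on an explicit "none" stage with an
  empty cancer-type selection. A record that merely skipped both questions
  is handled by the missingness rule instead — this keeps the (earlier)
  ineligibility stage from absorbing high-missingness records and preserves
  disjoint stage accounting.
- **Reporting convention.** Indicator percentages among eliminated records
  use, by default, the count of *all* excluded responses (stage 1 included)
  as denominator; a config switch restricts it to indicator-based
  eliminations. Percentages print half-up to one decimal, with a trailing
  `.0` dropped.
- **Test selection.** Group comparisons use Pearson chi-square without
  continuity correction; 2×2 tables with any expected cell <5 fall back to
  the two-sided Fisher exact test (probability-ordering rule); means use
  Welch's t with Satterthwaite degrees of freedom (robust to the unequal
  variances these groups show), with a pooled-t option. P values below
  0.001 print as "<.001". No multiplicity adjustment is applied.
- A non-empty honeypot value is exposed as an optional thirteenth indicator,
  disabled by default.

## The synthetic-data generator

`synthgen` emulates the study conditions this package was built around: a
cohort of 1977 responses — 569 legitimate, 327 ineligible (planted 28 non-US
/ 28 stage-0 / 27 no-diagnosis / 46 nonmelanoma-only / 149 high-missingness
/ 12 gender-contradictory / 37 sex-site-contradictory), and 1081 fraudulent
records planted with the study's per-indicator marginal totals (250, 283,
820, 56, 34, 107, 20, 11, 57, 986, 166, 78), every fraud record carrying at
least two indicators. Class profiles follow the study's comparison table:
legitimate respondents older (age ~N(55.9, 13.1²), breast-cancer-heavy,
mostly cisgender female), fraudulent ones younger (~N(41.4, 8.2²)) with more
late-onset cancers claimed at implausible ages.

Design points:

- **Exact marginals.** A greedy degree-sequence assignment gives each fraud
  record two indicators (largest remaining counts first), then spreads the
  leftovers, under incompatibility constraints: the two timeline codes are
  mutually exclusive by construction; off-topic text is never co-planted
  with duplicate-telehealth (a duplicated IT comment would make the
  duplicate partner off-topic too); duplicate emails are kept clean-format
  so a partner never accidentally trips the suspicious-email rule.
- **Constructive non-interference.** Records *not* planted with an indicator
  are built so the detector cannot fire: clean submissions sit on a
  6-minute daytime grid (gaps >5 min, outside the night window), clean
  identities are drawn from the bundled name/street lists with substring
  collisions filtered out, open texts are template+serial-number unique,
  and every claimed source postdates its dissemination date.
- **Timeline layout.** Bursts (default size 12, 2-minute gaps, ≥10-minute
  separation) and night submissions occupy October 9–11, 2020;
  pre-dissemination singletons (source incongruence without suspicious
  timing) sit on October 8 and 12; everything else follows from October 13.
  This mirrors a public link briefly exposed on social media: the fraud wave
  lands in a narrow early window, email-recruited responses trickle in
  after the email date.
- **Age routing.** All fraud ages are drawn from the class profile first and
  the under-40 draws are routed to rare-cancer plantings, so plantings do
  not bias the class age distribution (the marginal is preserved exactly up
  to pool exhaustion).
- **Probabilistic mode.** For noise experiments, each of five record-local
  indicators is planted independently with a common probability *p*; the
  expected pipeline sensitivity is then the closed-form binomial tail
  P(Bin(5, p) ≥ 2), which the evaluation reproduces within Monte-Carlo
  error.
- All randomness flows through one seeded `numpy.random.Generator`; a config
  is reproducible byte-for-byte.

**What passing tests do and do not show.** The generator instantiates the
rule patterns *exactly*, so exact recovery (sensitivity = specificity = 1)
demonstrates that the implementation computes the declared rules correctly —
not that the rules detect real-world fraud with that accuracy. Real
fraudsters produce messier signals (plausible-looking duplicate paraphrases,
VPN-shifted timestamps, real-looking addresses), real humans trip single
rules innocently, and the generator's open text is templated rather than
natural language. Detection performance on real cohorts is a validity
question the original screening answered by member checking, which is out
of scope here.

## Numerical and degenerate-input choices

- Timestamps must carry an explicit UTC offset (or be declared Eastern);
  DST is handled by comparing instants and rendering clock times in
  `America/New_York`.
- Unparseable cells degrade to missing answers rather than hard errors —
  screening must tolerate garbage input.
- A detector with insufficient inputs (missing DOB, unknown source, empty
  email) returns *not suspicious*; rules only fire on positive evidence.
- Zero-margin contingency tables raise a degenerate-table error; empty-level
  rows are dropped before single-select tests.
- Identical constant samples in the Welch test return t = 0, p = 1 rather
  than 0/0.
- Percentages round half-up (decimal arithmetic, not binary float rounding).

## Problem sizes used in the shipped checks

The test-suite and acceptance script run the full study-scale cohort
(1977 records), a 1000-fraud-record probabilistic-planting experiment, 100
small random cohorts for conservation/monotonicity invariants, and an
exhaustive Fisher-vs-enumeration sweep over all 2×2 tables with grand total
≤30 (~46,000 tables) — sizes chosen so the complete run finishes in well
under a minute apiece on one core.

## Known limitations

- Address validation is lexical/structural only; no geocoding or postal
  verification.
- The bundled name lists are small US-centric samples; names outside them
  cannot trip (or be cleared by) the list-based clauses.
- "Random-letter" scoring is heuristic and will miss pronounceable-gibberish
  generators; it can flag legitimate machine-generated addresses
  (e.g. corporate hashes).
- Cohort-level duplicate detection is exact-match after normalization;
  paraphrased duplicates pass.
- The comparison module reports unadjusted P values by design.
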