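# Methods

This package implements rule-based ("computable") phenotypes for
hemophagocytic lymphohistiocytosis (HLH) over a tabular EHR extract, the
downstream treated-versus-untreated comparison, and an exploratory
ferritin+fever screening analysis. This note records the operational
definitions, the numerical and design choices made where the problem was
genuinely open, what the synthetic data emulate, and the limitations of
both.

## The eight criteria and their operationalization

An episode is the evaluation window for the HLH-2004 clinical criteria:
an inpatient admission from start to discharge. Open-ended admissions
truncate at the study-window end (2025-05-31 by default); outpatient
contacts are treated as a same-day episode (the calendar day of the
visit). A criterion is met if it occurs at **any point** during the
episode; a test never performed is categorized as *not abnormal*, i.e.
false, never missing. This asymmetric missing-data rule is deliberate:
it mirrors how a screening rule would behave prospectively, and it means
sparsely tested criteria (sCD25, NK activity) are under- rather than
over-counted.

| criterion | rule | units / default |
|---|---|---|
| fever | one oral reading ≥38.3 °C, **or** a run of consecutive oral readings all ≥38.0 °C spanning ≥60 min with no intervening oral reading <38.0 °C | °C, minutes |
| splenomegaly | any in-episode note with a non-negated lexicon term | — |
| cytopenia | ≥2 of 3 lineages low anywhere in the episode: Hgb <90 g/L (<100 g/L under 28 days of age at collection), platelets <100×10⁹/L, neutrophils <1.0×10⁹/L | strict `<` |
| TG / fibrinogen | triglycerides ≥3.0 mmol/L or fibrinogen ≤1.5 g/L | inclusive |
| hemophagocytosis | any in-episode pathology report positive (text rule or adjudication) | — |
| low NK activity | any abnormal-low flag | 0/1 flag |
| ferritin | ≥500 µg/L | inclusive |
| sCD25 | ≥2400 U/mL | inclusive |

Diagnosis by criteria requires ≥5 of 8 (`criteria_required`,
configurable to support sensitivity analyses).

Numerical conventions worth flagging:

* **Fever sustained clause.** The run span is measured from the first
  to the last reading of the run, so a lone 38.1 °C reading never
  qualifies — a duration claim needs two timepoints. Whether the
  documented rule intends reading-to-reading span or interpolated
  duration is not decidable from its statement; the run-span convention
  is the conservative reading.
* **Cytopenia simultaneity.** Lineages need not be low at the same
  time; each lineage is assessed over the whole episode, consistent
  with the any-point-during-the-episode rule. A stricter same-calendar-
  day reading is available as `cytopenia_same_day` (default off).
* **Triglycerides.** Fasting status is not recorded in extracts; any
  value is used.
* **NK activity** is a boolean abnormal-low flag, not a numeric value,
  because "low" is defined against local laboratory references that
  vary by site and era.
* **Units are canonical per analyte** (ferritin µg/L, Hgb g/L, counts
  10⁹/L, TG mmol/L, fibrinogen g/L, sCD25 U/mL) and conversion is out
  of scope: silent unit inference is a classic source of phenotyping
  bugs, so extracts must be pre-converted.

## Text rules

A *word* is a maximal run of alphanumeric characters; punctuation
separates tokens. Splenomegaly terms ("splenomegaly", "big spleen",
"organomegaly", "enlarged spleen") are matched as exact token phrases,
left to right, longest phrase first, non-overlapping. A mention is
negated if any cue ("no", "none", "absence", "without", "negative")
occurs within the 3 tokens immediately preceding the **first** token of
the term. The window counts tokens only — it may cross a sentence
boundary, a deliberate convention since the rule is stated purely as
word distance. A note is positive if it has at least one non-negated
mention, so a negated mention never masks a later affirmed one.

Hemophagocytosis patterns ("h(a)emophagocytosis", "h(a)emophagocytic")
match as substrings of a token in pathology text, with the same negation
window. In the original workflow such matches were manually reviewed;
here an `adjudicated_positive` column carries chart-review labels when
available and overrides the text rule, and the automated negation rule
stands in when no adjudication is supplied. No stemming, no uncertainty
or experiencer handling: the scope is exactly the published rule plus a
negation guard.

## Cohorts and index encounters

* **ICD cohort**: any in-window diagnosis event coded D76.1 or D76.2,
  matched exactly after upper-casing and trimming (child codes do not
  match). Index = encounter of the first such code.
* **Plan cohort**: case-insensitive substring match of "hlh" /
  "hemophagocytosis" / "haemophagocytosis" against the display *or*
  protocol name; index = first application.
* **Criteria cohort**: index = encounter with the maximum criteria
  count, earliest start on ties (then encounter id); membership iff the
  maximum ≥ `criteria_required`.

Diagnosis or plan events not linked to an encounter resolve to the
in-window encounter containing the event timestamp, else the nearest
subsequent encounter, else no index. This keeps encounter-scoped
therapy queries well defined without inventing encounters.

The ferritin+fever screening set is **encounter-level**: every
in-window encounter meeting both entry criteria, multiple episodes per
patient allowed. Number needed to screen = `round(total / n_meeting)`.

## Therapy and outcomes

HLH-directed therapy is any dose of dexamethasone, methylprednisolone,
anakinra, ruxolitinib, cyclosporine, etoposide, or emapalumab;
chemotherapy status is a per-administration flag supplied by the
extract (or a config lookup), since no canonical chemotherapy list
exists. Exposure is classified both during the index episode window and
at any encounter. The therapy pattern (steroid-only / steroid-plus-
other / other-only) is judged from index-encounter drugs when any were
given there; "steroid" means dexamethasone or methylprednisolone, the
two corticosteroids in the directed list.

Outcomes anchor at the index encounter: length of stay in days,
ICU admission, in-hospital death (death date inside the interval or a
not-alive discharge flag), death within 30 days of the index start
(inclusive of day 30 — the anchor and inclusivity are conventions, as
"within 30 days of the visit" does not fix them), stem-cell transplant
after the index start, consulting services, age group at admission
(0–<1, 1–4, 5–14, ≥15 years), and the timing of the first HLH ICD code
relative to the index interval (before/during/after/never).

## Statistics

* Continuous: Wilcoxon rank-sum (normal approximation, tie and
  continuity corrections; `scipy.stats.mannwhitneyu`).
* Categorical 2×2: Fisher's exact test when any expected cell <5, else
  chi-square with continuity correction; k×2: chi-square. The expected-
  cell rule is the standard convention; the choice is recorded per row
  in the output.
* Risk differences are reported two ways: rates rounded to one decimal
  percentage point **before** differencing (matching how such tables
  are printed and how their differences are arithmetically consistent),
  and the unrounded difference with a Wald 95% CI,
  d ± 1.96·√(p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂).
* Median length-of-stay difference: percentile bootstrap, 2000
  within-group resamples, seeded. The CI method is a package choice; no
  standard is implied by a bare "with 95% confidence intervals".
* Degenerate tables (a zero margin) report no p-value rather than a
  fabricated one.

## Synthetic data

The generator is a stylized emulator, not a disease model: a latent
hyperinflammatory state (Bernoulli, default prevalence 0.08 — a
referral-center enrichment, chosen once) drives per-criterion
conditional probabilities at one peak episode per latent patient
(defaults approximate the high prevalences seen in confirmed cohorts:
ferritin 0.98, fever 0.92, cytopenia 0.91, TG/fibrinogen 0.93,
splenomegaly 0.90, sCD25 0.50, hemophagocytosis 0.15, NK 0.10), with
low background probabilities elsewhere. Treatment probability is a
non-decreasing function of the realized criteria count; coding, plan
application, ICU, services, length of stay (log-normal per stratum,
medians ≈33 d treated / ≈21 d untreated / ≈4 d background) and death
follow the treatment stratum.

Two properties make the generator usable as ground truth: every sampled
criterion flag is *realized faithfully* in the raw tables (a fever flag
becomes a temperature trajectory that satisfies the fever rule and a
false flag cannot accidentally satisfy it; affirmed/negated note
templates are labelled per document), and identical seeds give
bit-identical extracts (independent RNG substreams per generation
stage). What it does **not** emulate: free-text variety beyond
templates, referring-institution lab gaps, miscoding, vital-sign
waveforms, or any mechanistic link between criteria beyond the shared
latent state. Passing tests on synthetic data therefore demonstrate
*rule fidelity* (the engine computes the stated rules exactly), not
clinical validity of the rules on real notes and labs.

The deterministic *table fixtures* are different objects: extracts
built by direct placement (no sampling) whose group sizes and event
counts equal published-style contingency counts — 245 patients split
193/52 by index-encounter HLH-directed therapy with fixed counts for
every comparison row, and 1325 ferritin+fever encounters with 252 at
≥5 criteria. Flag matrices with exact column sums under row-sum
constraints are built with a Gale–Ryser-style greedy allocator. Two
published inconsistencies surface here: the untreated age-group counts
sum to 51 of 52 (the extra patient is placed in the 5–14 stratum), and
the treated "any ICD diagnosis" count (77) exceeds the sum of its
timing breakdown (72); the fixture reproduces the timing rows and
computes the any-ICD row from them. Printed LOS IQRs are not targeted —
only the medians, which the downstream estimates use.

## Problem sizes and determinism

Default analysis sizes: 400 synthetic patients for the end-to-end run,
2000 for generator-calibration checks, 245 and 1325 rows for the two
fixtures; the bootstrap uses 2000 resamples. All randomness flows from
explicit seeds (`numpy` `SeedSequence`); the pipeline writes a manifest
with config snapshot and per-artifact SHA-256 checksums, and re-running
with identical inputs reproduces identical bytes.

## Known limitations

* The episode convention for outpatient contacts (same calendar day) is
  a package choice; episodes spanning transfers or re-admissions are
  not merged.
* Negation handling is a 3-token window, not a full negation grammar;
  double negation and scope inversion ("cannot exclude splenomegaly")
  are out of scope.
* The comparison is descriptive: treatment is confounded by indication
  and no adjustment is attempted.
* Pre-admission documents do not contribute to an episode; referral
  records naming splenomegaly before transfer are invisible to the
  criteria engine.
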