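# hlh-phenotyping

Computable phenotypes for **hemophagocytic lymphohistiocytosis (HLH)**
over tabular EHR extracts, for clinical informaticians and outcomes
researchers who need to assemble HLH cohorts from structured and
free-text hospital data.

HLH is a life-threatening hyperinflammatory syndrome whose clinical
diagnosis rests on the HLH-2004 criteria: ≥5 of 8 of fever,
splenomegaly, cytopenia of ≥2 lineages (Hgb <90 g/L, <100 g/L in
infants <4 wk; platelets <100×10⁹/L; neutrophils <1.0×10⁹/L),
hypertriglyceridemia or hypofibrinogenemia (TG ≥3.0 mmol/L or
fibrinogen ≤1.5 g/L), hemophagocytosis on pathology, low NK-cell
activity, ferritin ≥500 µg/L, and sCD25 ≥2400 U/mL. Because none of
this is captured systematically in an EHR, the package implements and
compares three machine-evaluable cohort definitions:

1. **ICD-10 coding** — D76.1 or D76.2 diagnosis events;
2. **Treatment plans** — care-plan names containing "HLH" or
   "h(a)emophagocytosis";
3. **Clinical criteria** — per-encounter evaluation of the eight
   operationalized criteria, including an oral-fever rule (≥38.3 °C
   once, or ≥38.0 °C sustained ≥60 min), lab thresholds with a
   not-tested-means-not-abnormal rule, and free-text detection of
   splenomegaly/hemophagocytosis with a 3-word pre-term negation
   window.

On top of the cohorts it provides the index-encounter logic (maximum
criteria count, earliest on ties), three-set overlap counts, therapy
classification (chemotherapy and the seven HLH-directed drugs:
dexamethasone, methylprednisolone, anakinra, ruxolitinib, cyclosporine,
etoposide, emapalumab), clinical outcomes (LOS, ICU, in-hospital and
30-day mortality, SCT), the treated-vs-untreated comparison (Wilcoxon
rank-sum, χ²/Fisher, risk differences with Wald CIs, bootstrap CI on
the median-LOS difference), a ferritin+fever screening analysis with
number-needed-to-screen, and a seeded synthetic-EHR generator so the
entire pipeline runs and is tested without any protected data.

## Layout

```
src/hlh_phenotyping/   the library: io, text, criteria, cohorts,
                       outcomes, stats, synthetic, fixtures, pipeline, cli
analysis/              numbered drivers: 01_simulate, 02_phenotype,
                       03_compare_treated, 04_screening
scripts/acceptance.py  recomputes the headline numbers from scratch
docs/methods.md        operational definitions and design choices
```

## Worked example

```bash
python analysis/01_simulate.py        # 400-patient synthetic extract
python analysis/02_phenotype.py       # three cohorts + overlap
python analysis/03_compare_treated.py # 245-patient comparison fixture
python analysis/04_screening.py       # 1325-encounter screening fixture
```

`03_compare_treated.py` runs the full pipeline on a deterministic
245-patient extract (193 treated with HLH-directed therapy during the
index encounter, 52 untreated) and prints:

```
groups: 193 treated vs 52 untreated
in-hospital mortality: 15.0% vs 13.5% (difference 1.5 pp, Wald 95% CI -9.0 to 12.1)
30-day mortality: 16.6% vs 15.4% (difference 1.2 pp)
median LOS: 33.4 vs 20.8 days; difference 12.6 (bootstrap 95% CI 2.4 to 28.4), rank-sum p=2.97e-06
```

i.e. mortality is high and nearly identical in both groups (the
differences are 1.5 and 1.2 percentage points under round-first
arithmetic), while treated patients stay 12.6 days longer in median.
`04_screening.py` prints the screening view: of 1325 encounters with
high ferritin and fever, 252 (19%) meet ≥5 criteria — a number needed
to screen of 5 — and cytopenia remains common (44%) even below the
threshold.

The same objects are available as a library:

```python
import hlh_phenotyping as hp

config  = hp.load_config()                     # thresholds, lexicons, window
extract = hp.load_extract("results/extract")   # validated CSV bundle
profiles = hp.evaluate_extract(extract, config)        # 8 flags per encounter
cohorts  = hp.build_phenotypes(extract, profiles, config)
overlap  = hp.compute_overlap(cohorts)
```

or through the CLI: `hlh-phenotype generate out/ --seed 7 --n-patients 400`,
`hlh-phenotype phenotype out/ results/ --criteria-required 5`.

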