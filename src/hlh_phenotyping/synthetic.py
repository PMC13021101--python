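"""Seeded synthetic-EHR generator.

A stylized emulator of a single pediatric institution's extract, not a
mechanistic disease model: each patient carries a latent
hyperinflammatory state (Bernoulli), and the state drives correlated
criterion exceedances at one "peak" encounter, ICD coding, treatment-plan
application, HLH-directed treatment (probability monotone in the
realized criteria count), length of stay and death.  Every sampled
criterion flag is realized faithfully in the raw tables — a fever flag
becomes an oral-temperature trajectory satisfying the fever rule, a
splenomegaly flag becomes a note built from an affirmed template — so
generator labels are ground truth for the downstream engine, and the
observed per-criterion prevalence among latent-positive episodes
estimates the configured conditional probability.

Identical seeds produce bit-identical extracts.  Independent RNG
substreams (one per generation stage, split from the master seed) keep
the realization of one stage stable when another changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .config import StudyConfig
from .criteria import CRITERIA
from .io import EhrExtract, SERVICES, empty_extract

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "write_ground_truth"]


AFFIRMED_NOTE_TEMPLATES = (
    "Exam shows enlarged spleen and mild hepatomegaly.",
    "Abdominal ultrasound demonstrates splenomegaly.",
    "Marked organomegaly appreciated on examination.",
    "Palpable big spleen noted below the costal margin.",
)
NEGATED_NOTE_TEMPLATES = (
    "Abdomen soft, no splenomegaly appreciated.",
    "Imaging without organomegaly.",
    "There was absence of splenomegaly on exam.",
    "Negative for enlarged spleen on ultrasound.",
)
NEUTRAL_NOTE_TEMPLATES = (
    "Patient resting comfortably, afebrile overnight.",
    "Plan: continue broad-spectrum antibiotics and supportive care.",
    "Spleen not palpable; liver edge unremarkable.",
)
AFFIRMED_PATH_TEMPLATES = (
    "Bone marrow aspirate demonstrates hemophagocytosis.",
    "Frequent haemophagocytic macrophages identified in the marrow.",
)
NEGATED_PATH_TEMPLATES = (
    "No hemophagocytosis identified in the aspirate.",
    "Marrow without haemophagocytic activity.",
)
ADMISSION_DX = (
    "Fever",
    "Sepsis",
    "Leukemia",
    "Acute lymphoblastic leukemia",
    "Neutropenia",
    "Pneumonia",
    "Viral infection",
    "Dehydration",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic extract; defaults emulate a referral-center
    population enriched for hyperinflammation."""

    n_patients: int = 400
    seed: int = 0
    p_latent_hlh: float = 0.08
    # Conditional probability of each criterion at the peak episode of a
    # latent-positive patient, and at any episode of a latent-negative one.
    criterion_p_latent: dict = field(default_factory=lambda: {
        "fever": 0.92, "splenomegaly": 0.90, "cytopenia": 0.91,
        "tg_or_fibrinogen": 0.93, "hemophagocytosis": 0.15, "low_nk": 0.10,
        "ferritin": 0.98, "scd25": 0.50,
    })
    criterion_p_background: dict = field(default_factory=lambda: {
        "fever": 0.25, "splenomegaly": 0.04, "cytopenia": 0.12,
        "tg_or_fibrinogen": 0.05, "hemophagocytosis": 0.002, "low_nk": 0.005,
        "ferritin": 0.10, "scd25": 0.02,
    })
    # Probability the underlying test is ordered when the criterion flag
    # is false (flag-true episodes are measured by construction).
    p_test_ordered: dict = field(default_factory=lambda: {
        "cytopenia": 0.95, "tg_or_fibrinogen": 0.50, "ferritin": 0.70,
        "scd25": 0.25, "low_nk": 0.08, "hemophagocytosis": 0.05,
    })
    p_icd_given_latent: float = 0.75
    p_icd_given_not: float = 0.01
    p_plan_given_treated: float = 0.20
    # P(HLH-directed therapy at the episode | criteria count), counts 0..8;
    # must be non-decreasing.
    p_treat_given_criteria_count: tuple = (
        0.02, 0.03, 0.05, 0.10, 0.30, 0.75, 0.85, 0.92, 0.95,
    )
    steroid_only_share: float = 0.68
    steroid_plus_other_share: float = 0.29
    p_chemo_given_treated: float = 0.35
    p_chemo_background: float = 0.02
    # Mortality by stratum.
    p_death_treated: float = 0.15
    p_death_untreated_latent: float = 0.14
    p_death_background: float = 0.005
    # Length of stay: log-normal (mu of log-days, sigma) per stratum.
    los_lognorm_treated: tuple = (np.log(33.0), 0.85)
    los_lognorm_untreated_latent: tuple = (np.log(21.0), 0.75)
    los_lognorm_background: tuple = (np.log(4.0), 0.70)
    p_negated_note: float = 0.5   # among notes of spleen-negative episodes
    p_note_written: float = 0.85  # a note exists at all for a negative episode
    mean_extra_encounters: float = 0.8
    p_inpatient: float = 0.75
    p_icu_latent: float = 0.50
    p_icu_background: float = 0.05
    p_sct_given_treated: float = 0.07
    window_start: date = date(2018, 6, 2)
    window_end: date = date(2025, 5, 31)

    def __post_init__(self):
        probs = (
            [self.p_latent_hlh, self.p_icd_given_latent, self.p_icd_given_not,
             self.p_plan_given_treated, self.p_chemo_given_treated,
             self.p_chemo_background, self.p_death_treated,
             self.p_death_untreated_latent, self.p_death_background,
             self.p_negated_note, self.p_note_written, self.p_inpatient,
             self.p_icu_latent, self.p_icu_background, self.p_sct_given_treated,
             self.steroid_only_share, self.steroid_plus_other_share]
            + list(self.criterion_p_latent.values())
            + list(self.criterion_p_background.values())
            + list(self.p_test_ordered.values())
            + list(self.p_treat_given_criteria_count)
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        t = self.p_treat_given_criteria_count
        if len(t) != 9 or any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("p_treat_given_criteria_count must be a "
                             "non-decreasing 9-tuple for counts 0..8")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclass
class GroundTruth:
    """Generator-side labels: latent states and per-document text labels."""

    patients: pd.DataFrame  # patient_id, latent, treated, peak_encounter
    notes: pd.DataFrame     # patient_id, encounter_id, authored_at, label
    episodes: pd.DataFrame  # encounter_id + the 8 sampled criterion flags


def _pick(rng: np.random.Generator, seq):
    return seq[int(rng.integers(0, len(seq)))]


class _Builder:
    """Accumulates rows for every extract table."""

    def __init__(self):
        self.rows = {name: [] for name, _ in empty_extract().tables()}

    def add(self, table: str, **row):
        self.rows[table].append(row)

    def extract(self) -> EhrExtract:
        base = empty_extract()
        out = {}
        for name, empty in base.tables():
            if self.rows[name]:
                df = pd.DataFrame(self.rows[name], columns=list(empty.columns))
                for col in empty.columns:
                    if str(empty[col].dtype) == "boolean":
                        df[col] = df[col].astype("boolean")
                    elif str(empty[col].dtype).startswith("datetime"):
                        df[col] = pd.to_datetime(df[col])
                    elif str(empty[col].dtype) == "float64":
                        df[col] = df[col].astype(float)
                out[name] = df
            else:
                out[name] = empty
        return EhrExtract(**out)


def _realize_episode(
    b: _Builder, rng: np.random.Generator, cfg: GeneratorConfig,
    pid: str, eid: str, start: pd.Timestamp, end: pd.Timestamp,
    flags: dict, note_labels: list,
) -> None:
    """Write lab/temperature/note/pathology rows realizing the flags."""
    t0 = start + pd.Timedelta(hours=2)

    # Temperatures: daily normals plus the fever realization.
    n_days = max(1, min(5, int((end - start) / pd.Timedelta(days=1))))
    for k in range(n_days):
        b.add("temperatures", patient_id=pid, encounter_id=eid,
              taken_at=start + pd.Timedelta(days=k, hours=8),
              temperature_c=round(36.5 + 1.2 * rng.random(), 1), route="oral")
    if flags["fever"]:
        if rng.random() < 0.7:  # single spike
            b.add("temperatures", patient_id=pid, encounter_id=eid,
                  taken_at=t0, temperature_c=round(38.3 + 1.5 * rng.random(), 1),
                  route="oral")
        else:  # sustained 38.0-38.2 run over >= 1 h
            for m in (0, 35, 70):
                b.add("temperatures", patient_id=pid, encounter_id=eid,
                      taken_at=t0 + pd.Timedelta(minutes=m),
                      temperature_c=round(38.0 + 0.2 * rng.random(), 1), route="oral")
    elif rng.random() < 0.15:
        # Sub-hour low-grade distractor; never satisfies either clause.
        b.add("temperatures", patient_id=pid, encounter_id=eid,
              taken_at=t0, temperature_c=38.1, route="oral")
        b.add("temperatures", patient_id=pid, encounter_id=eid,
              taken_at=t0 + pd.Timedelta(minutes=25), temperature_c=37.4, route="oral")

    def lab(analyte, value, hours=4):
        b.add("labs", patient_id=pid, encounter_id=eid, analyte=analyte,
              value=float(value), collected_at=start + pd.Timedelta(hours=hours))

    if flags["cytopenia"]:
        lineages = ["hemoglobin", "platelets", "neutrophils"]
        n_low = 2 if rng.random() < 0.6 else 3
        low = list(rng.choice(lineages, size=n_low, replace=False))
        lab("hemoglobin", round(rng.uniform(55, 85), 1) if "hemoglobin" in low
            else round(rng.uniform(110, 140), 1))
        lab("platelets", round(rng.uniform(15, 95), 1) if "platelets" in low
            else round(rng.uniform(160, 400), 1))
        lab("neutrophils", round(rng.uniform(0.05, 0.9), 2) if "neutrophils" in low
            else round(rng.uniform(2.0, 8.0), 2))
    elif rng.random() < cfg.p_test_ordered["cytopenia"]:
        lab("hemoglobin", round(rng.uniform(110, 140), 1))
        lab("platelets", round(rng.uniform(160, 400), 1))
        lab("neutrophils", round(rng.uniform(2.0, 8.0), 2))

    if flags["tg_or_fibrinogen"]:
        if rng.random() < 0.5:
            lab("triglycerides", round(rng.uniform(3.0, 8.0), 2))
            lab("fibrinogen", round(rng.uniform(1.8, 4.0), 2))
        else:
            lab("triglycerides", round(rng.uniform(0.8, 2.5), 2))
            lab("fibrinogen", round(rng.uniform(0.3, 1.5), 2))
    elif rng.random() < cfg.p_test_ordered["tg_or_fibrinogen"]:
        lab("triglycerides", round(rng.uniform(0.8, 2.5), 2))
        lab("fibrinogen", round(rng.uniform(1.8, 4.0), 2))

    if flags["ferritin"]:
        lab("ferritin", round(rng.uniform(500, 20000), 0))
    elif rng.random() < cfg.p_test_ordered["ferritin"]:
        lab("ferritin", round(rng.uniform(15, 450), 0))

    if flags["scd25"]:
        lab("scd25", round(rng.uniform(2400, 30000), 0))
    elif rng.random() < cfg.p_test_ordered["scd25"]:
        lab("scd25", round(rng.uniform(200, 2000), 0))

    if flags["low_nk"]:
        lab("nk_activity", 1.0)
    elif rng.random() < cfg.p_test_ordered["low_nk"]:
        lab("nk_activity", 0.0)

    # Notes (splenomegaly) with ground-truth labels.
    note_time = start + pd.Timedelta(hours=6)
    if flags["splenomegaly"]:
        text = _pick(rng, AFFIRMED_NOTE_TEMPLATES)
        b.add("notes", patient_id=pid, encounter_id=eid, authored_at=note_time, text=text)
        note_labels.append(dict(patient_id=pid, encounter_id=eid,
                                authored_at=note_time, label=True))
        if rng.random() < 0.3:  # an extra negated note must not mask the affirmed one
            t2 = note_time + pd.Timedelta(hours=12)
            b.add("notes", patient_id=pid, encounter_id=eid, authored_at=t2,
                  text=_pick(rng, NEGATED_NOTE_TEMPLATES))
            note_labels.append(dict(patient_id=pid, encounter_id=eid,
                                    authored_at=t2, label=False))
    elif rng.random() < cfg.p_note_written:
        neg = rng.random() < cfg.p_negated_note
        text = _pick(rng, NEGATED_NOTE_TEMPLATES if neg else NEUTRAL_NOTE_TEMPLATES)
        b.add("notes", patient_id=pid, encounter_id=eid, authored_at=note_time, text=text)
        note_labels.append(dict(patient_id=pid, encounter_id=eid,
                                authored_at=note_time, label=False))

    path_time = min(start + pd.Timedelta(hours=30), end)  # short stays report early
    if flags["hemophagocytosis"]:
        b.add("pathology", patient_id=pid, encounter_id=eid,
              authored_at=path_time,
              text=_pick(rng, AFFIRMED_PATH_TEMPLATES), adjudicated_positive=None)
    elif rng.random() < cfg.p_test_ordered["hemophagocytosis"]:
        b.add("pathology", patient_id=pid, encounter_id=eid,
              authored_at=path_time,
              text=_pick(rng, NEGATED_PATH_TEMPLATES), adjudicated_positive=None)


def generate(config: GeneratorConfig) -> tuple[EhrExtract, GroundTruth]:
    """Generate a fully valid extract plus generator ground truth."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["latent", "demo", "encounters", "criteria", "realize",
         "treatment", "outcomes", "coding"],
        ss.spawn(8),
    )}
    b = _Builder()
    note_labels: list[dict] = []
    gt_patients: list[dict] = []
    gt_episodes: list[dict] = []

    w_start = pd.Timestamp(cfg.window_start)
    w_days = (pd.Timestamp(cfg.window_end) - w_start).days - 90

    latent = streams["latent"].random(cfg.n_patients) < cfg.p_latent_hlh

    for i in range(cfg.n_patients):
        pid = f"p{i + 1:05d}"
        rng_d = streams["demo"]
        sex = "male" if rng_d.random() < 0.52 else "female"
        age_days_at_entry = int(rng_d.integers(5, 18 * 365))
        entry = w_start + pd.Timedelta(days=int(streams["encounters"].integers(0, w_days)))
        birth = (entry - pd.Timedelta(days=age_days_at_entry)).normalize()
        is_latent = bool(latent[i])

        n_enc = 1 + int(streams["encounters"].poisson(cfg.mean_extra_encounters))
        peak_slot = int(streams["encounters"].integers(0, n_enc)) if is_latent else -1

        death_date = pd.NaT
        treated_any = False
        peak_eid = None
        enc_start = entry
        for j in range(n_enc):
            eid = f"{pid}e{j + 1}"
            rng_e = streams["encounters"]
            rng_c = streams["criteria"]
            rng_r = streams["realize"]
            rng_t = streams["treatment"]
            rng_o = streams["outcomes"]
            is_peak = j == peak_slot
            inpatient = is_peak or rng_e.random() < cfg.p_inpatient

            # Criterion flags for this episode; outpatient contacts carry
            # at most a ferritin draw.
            p = cfg.criterion_p_latent if is_peak else cfg.criterion_p_background
            flags = {c: bool(rng_c.random() < p[c]) for c in CRITERIA}
            if not inpatient:
                flags = {c: (flags[c] if c == "ferritin" else False) for c in CRITERIA}
            count = sum(flags.values())

            # Treatment decision, monotone in count.
            treat = rng_t.random() < cfg.p_treat_given_criteria_count[count]

            # Length of stay by stratum.
            if treat and (is_peak or is_latent):
                mu, sig = cfg.los_lognorm_treated
            elif is_peak:
                mu, sig = cfg.los_lognorm_untreated_latent
            else:
                mu, sig = cfg.los_lognorm_background
            los = max(0.5, float(rng_o.lognormal(mu, sig))) if inpatient else 0.0
            start = enc_start
            end = start + pd.Timedelta(days=los) if inpatient else start + pd.Timedelta(hours=4)
            start = start.floor("min")
            end = end.floor("min")

            if inpatient:
                _realize_episode(b, rng_r, cfg, pid, eid, start, end, flags, note_labels)
            elif flags["ferritin"]:
                # Drawn at visit start: outpatient episodes span one
                # calendar day, and visits can begin late in the evening.
                b.add("labs", patient_id=pid, encounter_id=eid, analyte="ferritin",
                      value=float(round(rng_r.uniform(500, 5000), 0)),
                      collected_at=start)

            gt_episodes.append(dict(encounter_id=eid, patient_id=pid,
                                    is_peak=is_peak, **flags))

            # Drugs.
            if treat:
                treated_any = True
                u = rng_t.random()
                if u < cfg.steroid_only_share:
                    drugs = ["dexamethasone"]
                elif u < cfg.steroid_only_share + cfg.steroid_plus_other_share:
                    drugs = ["dexamethasone", "anakinra"]
                else:
                    drugs = [_pick(rng_t, ["anakinra", "ruxolitinib", "emapalumab"])]
                for k, drug in enumerate(drugs):
                    b.add("medications", patient_id=pid, encounter_id=eid,
                          generic_name=drug,
                          administered_at=start + pd.Timedelta(hours=10 + k),
                          is_chemotherapy=drug == "etoposide")
                if rng_t.random() < cfg.p_chemo_given_treated:
                    drug = _pick(rng_t, ["etoposide", "cytarabine"])
                    b.add("medications", patient_id=pid, encounter_id=eid,
                          generic_name=drug,
                          administered_at=start + pd.Timedelta(hours=20),
                          is_chemotherapy=True)
                if rng_t.random() < cfg.p_plan_given_treated:
                    b.add("treatment_plans", patient_id=pid,
                          display_name="HLH-94 treatment plan",
                          protocol_name="HLH-94", applied_at=start + pd.Timedelta(hours=9),
                          encounter_id=eid)
            elif rng_t.random() < cfg.p_chemo_background:
                b.add("medications", patient_id=pid, encounter_id=eid,
                      generic_name="cytarabine",
                      administered_at=start + pd.Timedelta(hours=12),
                      is_chemotherapy=True)

            # Coding.
            p_icd = cfg.p_icd_given_latent if is_peak else cfg.p_icd_given_not
            if streams["coding"].random() < p_icd:
                b.add("diagnoses", patient_id=pid, icd10_code="D76.1",
                      noted_at=start + pd.Timedelta(days=1), encounter_id=eid)

            # ICU and services.
            p_icu = cfg.p_icu_latent if is_peak else cfg.p_icu_background
            if inpatient and rng_o.random() < p_icu:
                b.add("icu", patient_id=pid, encounter_id=eid,
                      start=start + pd.Timedelta(hours=12),
                      end=min(end, start + pd.Timedelta(days=3)))
            n_svc = int(rng_o.integers(2, 6)) if is_peak else int(rng_o.integers(0, 2))
            for s in rng_o.choice(SERVICES, size=n_svc, replace=False):
                b.add("services", patient_id=pid, encounter_id=eid, service=str(s))

            # Mortality.
            if treat and (is_peak or is_latent):
                p_death = cfg.p_death_treated
            elif is_peak:
                p_death = cfg.p_death_untreated_latent
            else:
                p_death = cfg.p_death_background
            died_here = pd.isna(death_date) and rng_o.random() < p_death
            discharged_alive = True
            if died_here:
                death_date = (start + pd.Timedelta(days=int(rng_o.integers(1, 26)))).normalize()
                if death_date <= end:
                    end = death_date + pd.Timedelta(hours=10)
                    discharged_alive = False

            if is_peak:
                peak_eid = eid
                if treat and rng_t.random() < cfg.p_sct_given_treated:
                    b.add("sct", patient_id=pid, date=(start + pd.Timedelta(days=60)).normalize())

            b.add("encounters", encounter_id=eid, patient_id=pid,
                  encounter_class="inpatient" if inpatient else "outpatient",
                  start=start, end=end,
                  admission_diagnosis=_pick(rng_e, ADMISSION_DX) if inpatient else None,
                  discharged_alive=discharged_alive if inpatient else None)

            enc_start = end + pd.Timedelta(days=int(rng_e.integers(20, 120)))
            if not pd.isna(death_date):
                break

        b.add("patients", patient_id=pid, sex=sex, birth_date=birth,
              death_date=death_date if not pd.isna(death_date) else None)
        gt_patients.append(dict(patient_id=pid, latent=is_latent,
                                treated=treated_any, peak_encounter=peak_eid))

    extract = b.extract()
    gt = GroundTruth(
        patients=pd.DataFrame(gt_patients),
        notes=pd.DataFrame(note_labels, columns=["patient_id", "encounter_id",
                                                 "authored_at", "label"]),
        episodes=pd.DataFrame(gt_episodes),
    )
    return extract, gt


def write_ground_truth(gt: GroundTruth, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt.patients.to_csv(directory / "ground_truth_patients.csv", index=False)
    gt.notes.to_csv(directory / "ground_truth_notes.csv", index=False)
    gt.episodes.to_csv(directory / "ground_truth_episodes.csv", index=False)
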