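"""Per-criterion rules, episode assembly, and brute-force equivalence."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import hlh_phenotyping as hp
from hlh_phenotyping.criteria import episode_window, evaluate_encounter
from hlh_phenotyping.synthetic import GeneratorConfig, generate
from hlh_phenotyping.text import (
    note_positive_for_splenomegaly,
    pathology_positive_for_hemophagocytosis,
)

from conftest import build_extract, one_patient_extract

CFG = hp.StudyConfig()
T0 = pd.Timestamp("2021-01-01 08:00")


def _temps(*readings):
    return [
        dict(patient_id="p1", encounter_id="e1",
             taken_at=T0 + pd.Timedelta(minutes=m), temperature_c=v, route=route)
        for m, v, route in readings
    ]


@pytest.mark.parametrize(
    "readings, met",
    [
        ([(0, 38.3, "oral")], True),                              # single spike
        ([(0, 38.1, "oral"), (65, 38.1, "oral")], True),          # 65-min run
        ([(0, 38.1, "oral"), (30, 37.5, "oral"), (65, 38.1, "oral")], False),
        ([(0, 38.1, "oral")], False),                             # span needs 2 points
        ([(0, 38.1, "oral"), (50, 38.2, "oral")], False),         # run only 50 min
        ([(0, 39.0, "other")], False),                            # non-oral ignored
        ([(0, 38.2, "oral"), (30, 38.0, "oral"), (61, 38.2, "oral")], True),
        ([], False),
    ],
)
def test_fever_rule(readings, met):
    extract = one_patient_extract(temperatures=_temps(*readings))
    prof = evaluate_encounter(extract, "e1", CFG)
    assert prof.flags["fever"] is met


def _lab(analyte, value, when="2021-01-02 08:00"):
    return dict(patient_id="p1", encounter_id="e1", analyte=analyte,
                value=value, collected_at=when)


@pytest.mark.parametrize(
    "labs, met",
    [
        ([_lab("hemoglobin", 85.0), _lab("platelets", 90.0)], True),
        ([_lab("platelets", 90.0)], False),
        ([_lab("hemoglobin", 95.0), _lab("platelets", 150.0)], False),
        ([_lab("neutrophils", 0.5), _lab("platelets", 99.9)], True),
        ([_lab("hemoglobin", 90.0), _lab("platelets", 100.0)], False),  # strict <
    ],
)
def test_cytopenia_two_of_three_lineages(labs, met):
    extract = one_patient_extract(labs=labs)
    assert evaluate_encounter(extract, "e1", CFG).flags["cytopenia"] is met


def test_infant_hemoglobin_threshold():
    # A 10-day-old with Hgb 95: low under the <100 g/L infant cutoff.
    extract = build_extract(
        patients=[dict(patient_id="p1", sex="male", birth_date="2020-12-25")],
        encounters=[dict(encounter_id="e1", patient_id="p1",
                         encounter_class="inpatient", start="2021-01-01 00:00",
                         end="2021-01-20 00:00")],
        labs=[_lab("hemoglobin", 95.0, "2021-01-04 08:00"),
              _lab("platelets", 50.0, "2021-01-04 08:00")],
    )
    assert evaluate_encounter(extract, "e1", CFG).flags["cytopenia"] is True
    # Same values at 2 months of age: not low.
    extract.patients.loc[0, "birth_date"] = pd.Timestamp("2020-11-01")
    assert evaluate_encounter(extract, "e1", CFG).flags["cytopenia"] is False


@pytest.mark.parametrize(
    "labs, criterion, met",
    [
        ([_lab("ferritin", 500.0)], "ferritin", True),     # inclusive >=
        ([_lab("ferritin", 499.9)], "ferritin", False),
        ([_lab("fibrinogen", 1.5)], "tg_or_fibrinogen", True),   # inclusive <=
        ([_lab("fibrinogen", 1.51)], "tg_or_fibrinogen", False),
        ([_lab("triglycerides", 3.0)], "tg_or_fibrinogen", True),
        ([_lab("scd25", 2400.0)], "scd25", True),
        ([_lab("scd25", 2399.0)], "scd25", False),
        ([], "scd25", False),                              # not performed => not abnormal
        ([_lab("nk_activity", 1.0)], "low_nk", True),
        ([_lab("nk_activity", 0.0)], "low_nk", False),
    ],
)
def test_lab_threshold_inclusivity_and_missingness(labs, criterion, met):
    extract = one_patient_extract(labs=labs)
    prof = evaluate_encounter(extract, "e1", CFG)
    assert prof.flags[criterion] is met
    if not labs:
        assert prof.measured[criterion] is False


def test_episode_window_rules(config):
    inpt = pd.Series(dict(encounter_class="inpatient",
                          start=pd.Timestamp("2021-01-01 10:00"),
                          end=pd.Timestamp("2021-01-10 12:00")))
    assert episode_window(inpt, config) == (
        pd.Timestamp("2021-01-01 10:00"), pd.Timestamp("2021-01-10 12:00"))
    open_enc = pd.Series(dict(encounter_class="inpatient",
                              start=pd.Timestamp("2025-05-01 10:00"), end=pd.NaT))
    _, end = episode_window(open_enc, config)
    assert end.date() == config.window_end
    outpt = pd.Series(dict(encounter_class="outpatient",
                           start=pd.Timestamp("2021-03-05 14:30"), end=pd.NaT))
    lo, hi = episode_window(outpt, config)
    assert lo == pd.Timestamp("2021-03-05") and hi.date() == lo.date()


def test_evaluate_encounter_composes_flags():
    extract = one_patient_extract(
        labs=[_lab("ferritin", 1200.0), _lab("hemoglobin", 80.0),
              _lab("platelets", 40.0), _lab("triglycerides", 3.5)],
        temperatures=_temps((0, 38.5, "oral")),
        notes=[dict(patient_id="p1", encounter_id="e1",
                    authored_at="2021-01-03 09:00",
                    text="Exam shows splenomegaly.")],
    )
    prof = evaluate_encounter(extract, "e1", CFG)
    assert prof.count == 5
    assert prof.flags == {
        "fever": True, "splenomegaly": True, "cytopenia": True,
        "tg_or_fibrinogen": True, "hemophagocytosis": False,
        "low_nk": False, "ferritin": True, "scd25": False,
    }
    empty = one_patient_extract()
    assert evaluate_encounter(empty, "e1", CFG).count == 0


def test_all_eight_criteria_satisfiable():
    extract = one_patient_extract(
        labs=[_lab("ferritin", 600.0), _lab("hemoglobin", 80.0),
              _lab("platelets", 40.0), _lab("triglycerides", 3.5),
              _lab("scd25", 3000.0), _lab("nk_activity", 1.0)],
        temperatures=_temps((0, 39.0, "oral")),
        notes=[dict(patient_id="p1", encounter_id="e1",
                    authored_at="2021-01-03 09:00", text="splenomegaly")],
        pathology=[dict(patient_id="p1", encounter_id="e1",
                        authored_at="2021-01-04 09:00",
                        text="hemophagocytosis seen", adjudicated_positive=None)],
    )
    assert evaluate_encounter(extract, "e1", CFG).count == 8


def test_encounter_outside_window_rejected():
    extract = build_extract(
        patients=[dict(patient_id="p1", sex="male", birth_date="2010-01-01")],
        encounters=[dict(encounter_id="e1", patient_id="p1",
                         encounter_class="inpatient", start="2017-01-01 00:00",
                         end="2017-01-05 00:00")],
    )
    with pytest.raises(ValueError, match="outside"):
        evaluate_encounter(extract, "e1", CFG)
    assert len(hp.evaluate_extract(extract, CFG)) == 0


def test_adding_rows_never_decreases_count():
    extract = one_patient_extract(
        labs=[_lab("ferritin", 1200.0)], temperatures=_temps((0, 38.5, "oral")),
    )
    base = evaluate_encounter(extract, "e1", CFG).count
    richer = one_patient_extract(
        labs=[_lab("ferritin", 1200.0), _lab("ferritin", 10.0),
              _lab("hemoglobin", 80.0), _lab("platelets", 40.0)],
        temperatures=_temps((0, 38.5, "oral"), (60, 36.5, "oral")),
        notes=[dict(patient_id="p1", encounter_id="e1",
                    authored_at="2021-01-03 09:00", text="no splenomegaly")],
    )
    assert evaluate_encounter(richer, "e1", CFG).count >= base


def test_row_order_invariance():
    extract, _ = generate(GeneratorConfig(n_patients=15, seed=3))
    prof1 = hp.evaluate_extract(extract, CFG)
    shuffled = extract.copy()
    rng = np.random.default_rng(0)
    for name, df in shuffled.tables():
        setattr(shuffled, name,
                df.sample(frac=1, random_state=rng.integers(2**31)).reset_index(drop=True))
    prof2 = hp.evaluate_extract(shuffled, CFG)
    pd.testing.assert_frame_equal(prof1, prof2)


# --- brute-force evaluator ---------------------------------------------

def brute_force_profile(extract, encounter_id, cfg):
    """Independent per-row scan of every criterion rule."""
    e = extract.encounters.set_index("encounter_id").loc[encounter_id]
    if e["encounter_class"] == "outpatient":
        lo = pd.Timestamp(e["start"]).normalize()
        hi = lo + pd.Timedelta(days=1) - pd.Timedelta(minutes=1)
    else:
        lo = pd.Timestamp(e["start"])
        hi = e["end"] if not pd.isna(e["end"]) else (
            pd.Timestamp(cfg.window_end) + pd.Timedelta(days=1) - pd.Timedelta(minutes=1))
    birth = extract.patients.set_index("patient_id").loc[e["patient_id"], "birth_date"]

    def rows(df, tcol):
        return [r for _, r in df.iterrows()
                if r["encounter_id"] == encounter_id and lo <= r[tcol] <= hi]

    labs = rows(extract.labs, "collected_at")
    temps = sorted(
        (r for r in rows(extract.temperatures, "taken_at") if r["route"] == "oral"),
        key=lambda r: r["taken_at"],
    )
    # Fever: single spike, or a pair (i, j) spanning >= 60 min with every
    # reading between them at or above 38.0.
    fever = any(r["temperature_c"] >= cfg.thresholds.fever_single for r in temps)
    if not fever:
        for i in range(len(temps)):
            for j in range(i + 1, len(temps)):
                span = temps[j]["taken_at"] - temps[i]["taken_at"]
                if span >= pd.Timedelta(minutes=60) and all(
                    temps[k]["temperature_c"] >= cfg.thresholds.fever_sustained_low
                    for k in range(i, j + 1)
                ):
                    fever = True

    def low(r):
        a, v = r["analyte"], r["value"]
        if a == "hemoglobin":
            infant = (r["collected_at"] - birth).days < cfg.thresholds.infant_age_days
            return v < (cfg.thresholds.hgb_max_infant if infant else cfg.thresholds.hgb_max)
        if a == "platelets":
            return v < cfg.thresholds.plt_max
        if a == "neutrophils":
            return v < cfg.thresholds.anc_max
        return False

    lineages = {r["analyte"] for r in labs if low(r)}
    flags = {
        "fever": fever,
        "splenomegaly": any(
            note_positive_for_splenomegaly(r["text"] or "", cfg)
            for r in rows(extract.notes, "authored_at")
        ),
        "cytopenia": len(lineages) >= 2,
        "tg_or_fibrinogen": any(
            (r["analyte"] == "triglycerides" and r["value"] >= cfg.thresholds.tg_min)
            or (r["analyte"] == "fibrinogen" and r["value"] <= cfg.thresholds.fib_max)
            for r in labs
        ),
        "hemophagocytosis": any(
            pathology_positive_for_hemophagocytosis(
                r["text"] or "", cfg,
                None if pd.isna(r["adjudicated_positive"]) else bool(r["adjudicated_positive"]),
            )
            for r in rows(extract.pathology, "authored_at")
        ),
        "low_nk": any(r["analyte"] == "nk_activity" and r["value"] > 0 for r in labs),
        "ferritin": any(
            r["analyte"] == "ferritin" and r["value"] >= cfg.thresholds.ferritin_min
            for r in labs
        ),
        "scd25": any(
            r["analyte"] == "scd25" and r["value"] >= cfg.thresholds.scd25_min
            for r in labs
        ),
    }
    return flags


@pytest.mark.parametrize("seed", range(12))
def test_engine_matches_brute_force_on_random_extracts(seed, config):
    gen = GeneratorConfig(n_patients=20, seed=1000 + seed)
    extract, _ = generate(gen)
    profiles = hp.evaluate_extract(extract, config).set_index("encounter_id")
    for eid in profiles.index:
        expected = brute_force_profile(extract, eid, config)
        got = {c: bool(profiles.loc[eid, c]) for c in hp.CRITERIA}
        assert got == expected, eid
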