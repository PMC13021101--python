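"""Therapy classification, outcome derivation, comparison, screening."""

import pandas as pd
import pytest

import hlh_phenotyping as hp
from conftest import build_extract

CFG = hp.StudyConfig()


def _exposure_extract(meds):
    return build_extract(
        patients=[dict(patient_id="p1", sex="male", birth_date="2012-01-01")],
        encounters=[
            dict(encounter_id="e1", patient_id="p1", encounter_class="inpatient",
                 start="2020-01-01 00:00", end="2020-01-10 00:00"),
            dict(encounter_id="e2", patient_id="p1", encounter_class="inpatient",
                 start="2020-06-01 00:00", end="2020-06-05 00:00"),
        ],
        medications=meds,
    )


def _med(name, when, chemo=False, enc="e1"):
    return dict(patient_id="p1", encounter_id=enc, generic_name=name,
                administered_at=when, is_chemotherapy=chemo)


def test_dexamethasone_during_index_is_steroid_only():
    extract = _exposure_extract([_med("dexamethasone", "2020-01-02 10:00")])
    exp = hp.classify_therapy(extract, {"p1": "e1"}, CFG).iloc[0]
    assert exp["hlh_directed_index_encounter"] and exp["hlh_directed_any_encounter"]
    assert not exp["chemo_any_encounter"]
    assert exp["therapy_pattern"] == "steroid_only"


def test_etoposide_outside_index_encounter():
    extract = _exposure_extract([_med("etoposide", "2020-06-02 10:00", chemo=True, enc="e2")])
    exp = hp.classify_therapy(extract, {"p1": "e1"}, CFG).iloc[0]
    assert exp["hlh_directed_any_encounter"] and not exp["hlh_directed_index_encounter"]
    assert exp["chemo_any_encounter"] and not exp["chemo_index_encounter"]
    assert exp["chemo_or_hlh_any"] and not exp["chemo_or_hlh_index"]


def test_steroid_plus_other_pattern():
    extract = _exposure_extract([
        _med("anakinra", "2020-01-02 10:00"),
        _med("methylprednisolone", "2020-01-03 10:00"),
    ])
    exp = hp.classify_therapy(extract, {"p1": "e1"}, CFG).iloc[0]
    assert exp["therapy_pattern"] == "steroid_plus_other"


def test_non_hlh_drug_alone_gives_none_pattern():
    extract = _exposure_extract([_med("vancomycin", "2020-01-02 10:00")])
    exp = hp.classify_therapy(extract, {"p1": "e1"}, CFG).iloc[0]
    assert not exp["hlh_directed_any_encounter"]
    assert exp["therapy_pattern"] == "none"


def test_exposure_monotonicity_invariants(table2_products):
    exp = table2_products["exposures"]
    assert (exp["chemo_index_encounter"] <= exp["chemo_any_encounter"]).all()
    assert (exp["hlh_directed_index_encounter"] <= exp["hlh_directed_any_encounter"]).all()
    assert (exp["chemo_or_hlh_index"] ==
            (exp["chemo_index_encounter"] | exp["hlh_directed_index_encounter"])).all()
    assert (exp["chemo_or_hlh_any"] ==
            (exp["chemo_any_encounter"] | exp["hlh_directed_any_encounter"])).all()


def _outcome_extract(death_date=None, end="2020-01-10 00:00", discharged_alive=True,
                     diagnoses=(), sct=()):
    return build_extract(
        patients=[dict(patient_id="p1", sex="male", birth_date="2012-01-01",
                       death_date=death_date)],
        encounters=[dict(encounter_id="e1", patient_id="p1",
                         encounter_class="inpatient", start="2020-01-01 00:00",
                         end=end, discharged_alive=discharged_alive)],
        diagnoses=diagnoses,
        sct=sct,
    )


def _assignments():
    return pd.DataFrame([dict(
        patient_id="p1", in_icd_cohort=False, in_plan_cohort=False,
        in_criteria_cohort=True, index_encounter_icd=None,
        index_encounter_plan=None, index_encounter_criteria="e1",
        max_criteria_count=5,
    )])


def test_death_on_day_30_boundary_is_inclusive():
    extract = _outcome_extract(death_date="2020-01-31")  # start + 30 days
    out = hp.derive_outcomes(extract, _assignments(), CFG).iloc[0]
    assert out["death_within_30d"] and not out["in_hospital_death"]


def test_death_on_day_40_counts_for_neither():
    extract = _outcome_extract(death_date="2020-02-10")
    out = hp.derive_outcomes(extract, _assignments(), CFG).iloc[0]
    assert not out["death_within_30d"] and not out["in_hospital_death"]


def test_in_hospital_death_within_interval():
    extract = _outcome_extract(death_date="2020-01-05", discharged_alive=False)
    out = hp.derive_outcomes(extract, _assignments(), CFG).iloc[0]
    assert out["in_hospital_death"] and out["death_within_30d"]


def test_icd_timing_before_during_after_never():
    for noted, expected in [("2019-12-01 00:00", "before"),
                            ("2020-01-05 00:00", "during"),
                            ("2020-03-01 00:00", "after")]:
        extract = _outcome_extract(
            diagnoses=[dict(patient_id="p1", icd10_code="D76.1", noted_at=noted)])
        assert hp.derive_outcomes(extract, _assignments(), CFG).iloc[0]["icd_timing"] == expected
    extract = _outcome_extract()
    assert hp.derive_outcomes(extract, _assignments(), CFG).iloc[0]["icd_timing"] == "never"


def test_sct_after_and_los():
    extract = _outcome_extract(sct=[dict(patient_id="p1", date="2020-03-01")])
    out = hp.derive_outcomes(extract, _assignments(), CFG).iloc[0]
    assert out["sct_after"]
    assert out["los_days"] == pytest.approx(9.0)
    assert out["age_group"] == "5-14"


def test_missing_index_encounter_is_an_error():
    extract = _outcome_extract()
    broken = _assignments()
    broken.loc[0, "index_encounter_criteria"] = None
    with pytest.raises(ValueError, match="no index encounter"):
        hp.derive_outcomes(extract, broken, CFG)


def test_compare_groups_antisymmetry(table2_products, config):
    """Swapping the group labels negates the risk and median differences."""
    p = table2_products
    flipped = p["exposures"].copy()
    flipped["hlh_directed_index_encounter"] = ~flipped["hlh_directed_index_encounter"]
    rep = hp.compare_groups(p["extract"], p["profiles"], p["assignments"],
                            flipped, p["outcomes"], config, seed=11)
    orig = p["report"]
    assert rep.n_treated == orig.n_untreated
    assert rep.in_hospital_rd.diff_pct == pytest.approx(-orig.in_hospital_rd.diff_pct)
    assert rep.mortality30_rd.diff_pct == pytest.approx(-orig.mortality30_rd.diff_pct)
    assert rep.los["median_difference"] == pytest.approx(-orig.los["median_difference"])


def test_top5_admission_diagnoses_counting_and_ties():
    # "Apnea" and "Bronchiolitis" tie at 2; lexical order breaks the tie
    # for the fifth slot against "Croup" (also 2): Apnea, Bronchiolitis, Croup.
    labels = (["Fever"] * 4 + ["Sepsis"] * 3 + ["Apnea"] * 2 + ["Bronchiolitis"] * 2
              + ["Croup"] * 2 + ["Dehydration"])
    patients, encounters, labs, temps, notes = [], [], [], [], []
    for i, lab in enumerate(labels):
        pid, eid = f"p{i}", f"e{i}"
        patients.append(dict(patient_id=pid, sex="male", birth_date="2012-01-01"))
        encounters.append(dict(encounter_id=eid, patient_id=pid,
                               encounter_class="inpatient",
                               start="2020-01-01 00:00", end="2020-01-08 00:00",
                               admission_diagnosis=lab, discharged_alive=True))
        for analyte, value in [("ferritin", 900.0), ("hemoglobin", 70.0),
                               ("platelets", 50.0), ("triglycerides", 4.0)]:
            labs.append(dict(patient_id=pid, encounter_id=eid, analyte=analyte,
                             value=value, collected_at="2020-01-02 08:00"))
        temps.append(dict(patient_id=pid, encounter_id=eid,
                          taken_at="2020-01-02 08:00", temperature_c=39.0,
                          route="oral"))
        notes.append(dict(patient_id=pid, encounter_id=eid,
                          authored_at="2020-01-03 08:00",
                          text="Exam shows splenomegaly."))
    # Treat half so both groups are non-empty.
    meds = [dict(patient_id=f"p{i}", encounter_id=f"e{i}",
                 generic_name="dexamethasone", administered_at="2020-01-02 10:00",
                 is_chemotherapy=False) for i in range(0, len(labels), 2)]
    extract = build_extract(patients=patients, encounters=encounters, labs=labs,
                            temperatures=temps, notes=notes, medications=meds)
    profiles = hp.evaluate_extract(extract, CFG)
    assert (profiles["count"] >= 5).all()
    asn = hp.build_phenotypes(extract, profiles, CFG)
    members = asn[asn["in_criteria_cohort"]]
    idx = pd.Series(members["index_encounter_criteria"].values,
                    index=members["patient_id"].values)
    exp = hp.classify_therapy(extract, idx, CFG)
    out = hp.derive_outcomes(extract, asn, CFG)
    rep = hp.compare_groups(extract, profiles, asn, exp, out, CFG)
    assert rep.top5_admission_dx == ["Fever", "Sepsis", "Apnea", "Bronchiolitis", "Croup"]


def test_screening_summary_partition_and_edge_cases():
    cols = list(hp.CRITERIA) + [f"measured_{c}" for c in hp.CRITERIA]
    rows = []
    for i, count in enumerate([5, 6, 3, 2]):
        rec = dict(encounter_id=f"e{i}", patient_id=f"p{i}",
                   start=pd.Timestamp("2020-01-01"), count=count,
                   meets_threshold=count >= 5)
        for c in cols:
            rec[c] = True
        rows.append(rec)
    scr = pd.DataFrame(rows)
    ss = hp.screening_summary(scr)
    assert ss.total_encounters == 4 and ss.n_meeting == 2 and ss.n_below == 2
    assert ss.n_meeting + ss.n_below == ss.total_encounters
    assert ss.share_meeting_pct == 50.0
    assert ss.number_needed_to_screen == 2.0

    all_meet = scr[scr["meets_threshold"]]
    assert hp.screening_summary(all_meet).number_needed_to_screen == 1.0

    empty = hp.screening_summary(scr.iloc[0:0])
    assert empty.total_encounters == 0
    assert pd.isna(empty.number_needed_to_screen)
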