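"""Cohort construction, index-encounter selection, overlap, screening."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hlh_phenotyping as hp
from conftest import build_extract

CFG = hp.StudyConfig()


def _two_encounter_extract(diagnoses=(), treatment_plans=()):
    return build_extract(
        patients=[dict(patient_id="p1", sex="male", birth_date="2012-01-01")],
        encounters=[
            dict(encounter_id="e1", patient_id="p1", encounter_class="inpatient",
                 start="2020-01-01 00:00", end="2020-01-10 00:00"),
            dict(encounter_id="e2", patient_id="p1", encounter_class="inpatient",
                 start="2021-06-01 00:00", end="2021-06-10 00:00"),
        ],
        diagnoses=diagnoses,
        treatment_plans=treatment_plans,
    )


def test_icd_cohort_first_code_and_exact_match():
    extract = _two_encounter_extract(diagnoses=[
        dict(patient_id="p1", icd10_code="D76.1", noted_at="2021-06-02 00:00",
             encounter_id="e2"),
        dict(patient_id="p1", icd10_code="D76.1", noted_at="2020-01-02 00:00",
             encounter_id="e1"),
        dict(patient_id="p1", icd10_code="D76.3", noted_at="2019-01-02 00:00"),
    ])
    cohort = hp.build_icd_cohort(extract, CFG)
    assert list(cohort["patient_id"]) == ["p1"]
    assert cohort.iloc[0]["index_encounter"] == "e1"   # earlier of the two D76.1


def test_icd_code_before_window_excluded():
    extract = _two_encounter_extract(diagnoses=[
        dict(patient_id="p1", icd10_code="D76.1", noted_at="2018-05-01 00:00"),
    ])
    assert hp.build_icd_cohort(extract, CFG).empty


def test_unlinked_event_resolves_to_containing_then_next_encounter():
    extract = _two_encounter_extract(diagnoses=[
        dict(patient_id="p1", icd10_code="D76.2", noted_at="2020-01-05 00:00"),
    ])
    assert hp.build_icd_cohort(extract, CFG).iloc[0]["index_encounter"] == "e1"
    extract2 = _two_encounter_extract(diagnoses=[
        dict(patient_id="p1", icd10_code="D76.2", noted_at="2021-01-05 00:00"),
    ])
    assert hp.build_icd_cohort(extract2, CFG).iloc[0]["index_encounter"] == "e2"


@pytest.mark.parametrize(
    "display, member",
    [
        ("HLH-94 salvage", True),
        ("Hodgkin ABVD", False),
        ("haemophagocytosis protocol", True),
        ("Hemophagocytosis workup plan", True),
    ],
)
def test_plan_cohort_substring_match(display, member):
    extract = _two_encounter_extract(treatment_plans=[
        dict(patient_id="p1", display_name=display, protocol_name=None,
             applied_at="2020-01-02 00:00", encounter_id="e1"),
    ])
    assert (len(hp.build_plan_cohort(extract, CFG)) == 1) is member


def test_plan_protocol_name_also_matched():
    extract = _two_encounter_extract(treatment_plans=[
        dict(patient_id="p1", display_name="Oncology plan A", protocol_name="HLH-2004",
             applied_at="2020-01-02 00:00", encounter_id="e1"),
    ])
    assert len(hp.build_plan_cohort(extract, CFG)) == 1


def _profiles(rows):
    recs = []
    for pid, eid, start, count in rows:
        rec = dict(encounter_id=eid, patient_id=pid, start=pd.Timestamp(start),
                   count=count)
        for c in hp.CRITERIA:
            rec[c] = False
            rec[f"measured_{c}"] = False
        recs.append(rec)
    return pd.DataFrame(recs)


def test_criteria_cohort_argmax_and_tie_break():
    prof = _profiles([
        ("p1", "a", "2020-01-01", 4),
        ("p1", "b", "2020-06-01", 6),
        ("p2", "c", "2020-01-01", 5),
        ("p2", "d", "2019-05-01", 5),
        ("p3", "e", "2020-01-01", 4),
    ])
    cohort = hp.build_criteria_cohort(prof, CFG).set_index("patient_id")
    assert cohort.loc["p1", "index_encounter"] == "b" and cohort.loc["p1", "member"]
    assert cohort.loc["p2", "index_encounter"] == "d"   # tie -> earliest start
    assert not cohort.loc["p3", "member"]
    assert cohort.loc["p3", "max_criteria_count"] == 4  # recorded for non-members


def test_criteria_cohort_order_invariant():
    prof = _profiles([
        ("p1", "a", "2020-01-01", 5),
        ("p1", "b", "2020-01-01", 5),   # same start: id tie-break
    ])
    a = hp.build_criteria_cohort(prof, CFG)
    b = hp.build_criteria_cohort(prof.iloc[::-1].reset_index(drop=True), CFG)
    pd.testing.assert_frame_equal(a, b)
    assert a.iloc[0]["index_encounter"] == "a"


def _assignment(pid, icd, plan, crit):
    return dict(patient_id=pid, in_icd_cohort=icd, in_plan_cohort=plan,
                in_criteria_cohort=crit, index_encounter_icd=None,
                index_encounter_plan=None, index_encounter_criteria=None,
                max_criteria_count=0)


def test_overlap_examples():
    asn = pd.DataFrame([
        _assignment("a", True, False, False),
        _assignment("b", False, True, False),
        _assignment("c", False, False, True),
    ])
    ov = hp.compute_overlap(asn)
    assert (ov["icd_only"], ov["plan_only"], ov["criteria_only"]) == (1, 1, 1)
    assert ov["all_three"] == 0 and ov["union"] == 3

    asn = pd.DataFrame([_assignment("a", True, True, True)])
    ov = hp.compute_overlap(asn)
    assert ov["all_three"] == 1 and ov["union"] == 1


def test_overlap_matches_set_algebra_oracle():
    rng = np.random.default_rng(42)
    member = rng.random((50, 3)) < 0.4
    asn = pd.DataFrame([
        _assignment(f"p{i}", *member[i]) for i in range(50)
    ])
    ov = hp.compute_overlap(asn)
    sets = {k: {i for i in range(50) if member[i, j]} for j, k in enumerate("IPC")}
    expected = {
        "icd_only": sets["I"] - sets["P"] - sets["C"],
        "plan_only": sets["P"] - sets["I"] - sets["C"],
        "criteria_only": sets["C"] - sets["I"] - sets["P"],
        "icd_plan": (sets["I"] & sets["P"]) - sets["C"],
        "icd_criteria": (sets["I"] & sets["C"]) - sets["P"],
        "plan_criteria": (sets["P"] & sets["C"]) - sets["I"],
        "all_three": sets["I"] & sets["P"] & sets["C"],
    }
    for k, s in expected.items():
        assert ov[k] == len(s), k
    assert ov["union"] == len(sets["I"] | sets["P"] | sets["C"])
    assert ov["n_icd"] == len(sets["I"])
    # Region counts always reconcile with the union.
    assert ov["union"] == sum(ov[r] for r in
                              ("icd_only", "plan_only", "criteria_only", "icd_plan",
                               "icd_criteria", "plan_criteria", "all_three"))


def test_screening_cohort_is_encounter_level_and_requires_both_flags():
    prof = _profiles([
        ("p1", "a", "2020-01-01", 2),
        ("p1", "b", "2020-06-01", 5),
        ("p2", "c", "2020-01-01", 3),
    ])
    prof.loc[0, ["ferritin", "fever"]] = True
    prof.loc[1, ["ferritin", "fever"]] = True
    prof.loc[2, "ferritin"] = True   # fever missing -> excluded
    scr = hp.build_screening_cohort(prof, CFG)
    assert list(scr["encounter_id"]) == ["a", "b"]   # two rows, same patient
    assert scr["ferritin"].all() and scr["fever"].all()
    assert list(scr["meets_threshold"]) == [False, True]
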