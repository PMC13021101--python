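"""Shared fixtures: default config, small hand-built extracts, and the
deterministic table fixtures (built once per session)."""

from __future__ import annotations

import pandas as pd
import pytest

import hlh_phenotyping as hp
from hlh_phenotyping.fixtures import table2_fixture, table3_fixture
from hlh_phenotyping.io import empty_extract


@pytest.fixture(scope="session")
def config() -> hp.StudyConfig:
    return hp.StudyConfig()


def build_extract(
    patients=(), encounters=(), labs=(), temperatures=(), diagnoses=(),
    treatment_plans=(), medications=(), notes=(), pathology=(), icu=(),
    services=(), sct=(),
) -> hp.EhrExtract:
    """Hand-build a typed extract from row dicts (missing fields null)."""
    base = empty_extract()
    parts = dict(
        patients=patients, encounters=encounters, labs=labs,
        temperatures=temperatures, diagnoses=diagnoses,
        treatment_plans=treatment_plans, medications=medications,
        notes=notes, pathology=pathology, icu=icu, services=services, sct=sct,
    )
    out = {}
    for name, empty in base.tables():
        rows = list(parts[name])
        if not rows:
            out[name] = empty
            continue
        df = pd.DataFrame(rows)
        for col in empty.columns:
            if col not in df.columns:
                df[col] = None
        df = df[list(empty.columns)]
        for col in empty.columns:
            dtype = str(empty[col].dtype)
            if dtype == "boolean":
                df[col] = df[col].astype("boolean")
            elif dtype.startswith("datetime"):
                df[col] = pd.to_datetime(df[col])
            elif dtype == "float64":
                df[col] = df[col].astype(float)
        out[name] = df
    return hp.EhrExtract(**out)


def one_patient_extract(**tables) -> hp.EhrExtract:
    """An extract with one patient and one inpatient encounter ``e1``."""
    tables.setdefault(
        "patients",
        [dict(patient_id="p1", sex="female", birth_date="2015-01-01")],
    )
    tables.setdefault(
        "encounters",
        [dict(encounter_id="e1", patient_id="p1", encounter_class="inpatient",
              start="2021-01-01 00:00", end="2021-01-10 00:00",
              discharged_alive=True)],
    )
    return build_extract(**tables)


@pytest.fixture(scope="session")
def table2_products(config):
    """Fixture extract plus every downstream product, computed once."""
    extract = table2_fixture()
    profiles = hp.evaluate_extract(extract, config)
    assignments = hp.build_phenotypes(extract, profiles, config)
    members = assignments[assignments["in_criteria_cohort"]]
    idx = pd.Series(
        members["index_encounter_criteria"].values, index=members["patient_id"].values
    )
    exposures = hp.classify_therapy(extract, idx, config)
    outcome_df = hp.derive_outcomes(extract, assignments, config)
    report = hp.compare_groups(
        extract, profiles, assignments, exposures, outcome_df, config, seed=11
    )
    return dict(
        extract=extract, profiles=profiles, assignments=assignments,
        exposures=exposures, outcomes=outcome_df, report=report,
    )


@pytest.fixture(scope="session")
def table3_products(config):
    extract = table3_fixture()
    profiles = hp.evaluate_extract(extract, config)
    screening = hp.build_screening_cohort(profiles, config)
    return dict(
        extract=extract, profiles=profiles, screening=screening,
        summary=hp.screening_summary(screening),
    )
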