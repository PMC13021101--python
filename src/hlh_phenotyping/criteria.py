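"""Per-episode evaluation of the eight HLH-2004 clinical criteria.

The evaluation window is an *episode*: an inpatient admission from start
to discharge (open-ended admissions truncate at the study window end;
outpatient contacts count as a same-day episode).  A criterion is met if
it occurs at any point during the episode; a test never performed is
"not abnormal", i.e. the criterion is false, never missing.

The eight criteria and their operationalizations:

* fever — one oral reading ≥38.3 °C, or a run of consecutive oral
  readings all ≥38.0 °C whose first-to-last span is ≥60 minutes with no
  intervening oral reading below 38.0 °C;
* splenomegaly — any in-episode note with a non-negated lexicon term;
* cytopenia — ≥2 of 3 lineages low anywhere in the episode
  (hemoglobin <90 g/L, <100 g/L under 28 days of age; platelets
  <100×10⁹/L; neutrophils <1.0×10⁹/L);
* hypertriglyceridemia/hypofibrinogenemia — triglycerides ≥3.0 mmol/L or
  fibrinogen ≤1.5 g/L;
* hemophagocytosis — any in-episode pathology report positive;
* low NK activity — any abnormal-low NK flag;
* ferritin ≥500 µg/L;
* sCD25 ≥2400 U/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import StudyConfig
from .io import EhrExtract
from .text import note_positive_for_splenomegaly, pathology_positive_for_hemophagocytosis

__all__ = [
    "CRITERIA",
    "CriteriaProfile",
    "episode_window",
    "fever_met",
    "cytopenia_met",
    "tg_fib_met",
    "ferritin_met",
    "scd25_met",
    "nk_met",
    "evaluate_encounter",
    "evaluate_extract",
]

CRITERIA = (
    "fever",
    "splenomegaly",
    "cytopenia",
    "tg_or_fibrinogen",
    "hemophagocytosis",
    "low_nk",
    "ferritin",
    "scd25",
)


@dataclass(frozen=True)
class CriteriaProfile:
    """Eight criterion flags for one encounter, with measurement status."""

    encounter_id: str
    patient_id: str
    flags: dict
    measured: dict
    count: int

    def __post_init__(self):
        assert self.count == sum(bool(v) for v in self.flags.values())


def episode_window(encounter: pd.Series, config: StudyConfig) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Inclusive ``[start, end]`` evaluation interval for an encounter.

    Open-ended encounters (still admitted) truncate at the study window
    end; outpatient contacts map to the calendar day of the visit.
    """
    start = pd.Timestamp(encounter["start"])
    if encounter.get("encounter_class") == "outpatient":
        day = start.normalize()
        return day, day + pd.Timedelta(days=1) - pd.Timedelta(minutes=1)
    end = encounter.get("end")
    if pd.isna(end):
        end = pd.Timestamp(config.window_end) + pd.Timedelta(days=1) - pd.Timedelta(minutes=1)
    return start, pd.Timestamp(end)


def fever_met(temps: pd.DataFrame, config: StudyConfig) -> bool:
    """Two-clause oral fever rule over the episode's temperature series.

    The sustained clause needs at least two readings: the run span is
    measured first reading to last, so a lone 38.1 °C never qualifies.
    """
    thr = config.thresholds
    oral = temps[temps["route"] == "oral"].sort_values("taken_at", kind="mergesort")
    if oral.empty:
        return False
    vals = oral["temperature_c"].to_numpy()
    if (vals >= thr.fever_single).any():
        return True
    times = oral["taken_at"].to_numpy()
    run_start = None
    best = pd.Timedelta(0)
    for v, t in zip(vals, times):
        if v >= thr.fever_sustained_low:
            if run_start is None:
                run_start = t
            best = max(best, pd.Timestamp(t) - pd.Timestamp(run_start))
        else:
            run_start = None
    return best >= pd.Timedelta(minutes=thr.fever_sustained_minutes)


def _lineage_low(labs: pd.DataFrame, birth_date, config: StudyConfig) -> pd.DataFrame:
    """Rows of the three cytopenia lineages with a per-row low flag."""
    thr = config.thresholds
    sub = labs[labs["analyte"].isin(["hemoglobin", "platelets", "neutrophils"])].copy()
    if sub.empty:
        sub["low"] = pd.Series([], dtype=bool)
        return sub
    age_days = (sub["collected_at"] - pd.Timestamp(birth_date)).dt.days.to_numpy()
    an = sub["analyte"].to_numpy()
    vals = sub["value"].to_numpy(dtype=float)
    import numpy as np

    hgb_cut = np.where(age_days < thr.infant_age_days, thr.hgb_max_infant, thr.hgb_max)
    cut = np.where(
        an == "hemoglobin", hgb_cut,
        np.where(an == "platelets", thr.plt_max, thr.anc_max),
    )
    sub["low"] = vals < cut
    return sub


def cytopenia_met(labs: pd.DataFrame, birth_date, config: StudyConfig) -> bool:
    """≥2 lineages low; by default each lineage is assessed over the whole
    episode independently (``cytopenia_same_day`` tightens to one day)."""
    sub = _lineage_low(labs, birth_date, config)
    if sub.empty:
        return False
    low = sub[sub["low"]]
    if config.cytopenia_same_day:
        per_day = low.groupby(low["collected_at"].dt.date)["analyte"].nunique()
        return bool((per_day >= 2).any())
    return low["analyte"].nunique() >= 2


def _any_value(labs, analyte, op, threshold) -> bool:
    vals = labs.loc[labs["analyte"] == analyte, "value"]
    if vals.empty:
        return False
    if op == "ge":
        return bool((vals >= threshold).any())
    return bool((vals <= threshold).any())


def tg_fib_met(labs: pd.DataFrame, config: StudyConfig) -> bool:
    thr = config.thresholds
    return _any_value(labs, "triglycerides", "ge", thr.tg_min) or _any_value(
        labs, "fibrinogen", "le", thr.fib_max
    )


def ferritin_met(labs: pd.DataFrame, config: StudyConfig) -> bool:
    return _any_value(labs, "ferritin", "ge", config.thresholds.ferritin_min)


def scd25_met(labs: pd.DataFrame, config: StudyConfig) -> bool:
    return _any_value(labs, "scd25", "ge", config.thresholds.scd25_min)


def nk_met(labs: pd.DataFrame, config: StudyConfig) -> bool:
    """NK activity is a 0/1 abnormal-low flag in the value column."""
    vals = labs.loc[labs["analyte"] == "nk_activity", "value"]
    return bool((vals > 0).any())


def _measured(labs, analytes) -> bool:
    return bool(labs["analyte"].isin(analytes).any())


def _in_window(df, col, window):
    start, end = window
    return df[(df[col] >= start) & (df[col] <= end)]


def evaluate_encounter(
    extract: EhrExtract, encounter: pd.Series | str, config: StudyConfig
) -> CriteriaProfile:
    """Evaluate all eight criteria for one encounter.

    A pure function of the extract slice linked to the encounter and
    falling inside its episode window.  Raises ``ValueError`` for an
    encounter outside the study window.
    """
    if isinstance(encounter, str):
        rows = extract.encounters[extract.encounters["encounter_id"] == encounter]
        if rows.empty:
            raise KeyError(f"unknown encounter {encounter!r}")
        encounter = rows.iloc[0]
    start_day = pd.Timestamp(encounter["start"]).date()
    if not (config.window_start <= start_day <= config.window_end):
        raise ValueError(
            f"encounter {encounter['encounter_id']} starts {start_day}, outside "
            f"study window {config.window_start}..{config.window_end}"
        )
    eid = encounter["encounter_id"]
    window = episode_window(encounter, config)

    labs = _in_window(
        extract.labs[extract.labs["encounter_id"] == eid], "collected_at", window
    )
    temps = _in_window(
        extract.temperatures[extract.temperatures["encounter_id"] == eid],
        "taken_at",
        window,
    )
    notes = _in_window(
        extract.notes[extract.notes["encounter_id"] == eid], "authored_at", window
    )
    path = _in_window(
        extract.pathology[extract.pathology["encounter_id"] == eid], "authored_at", window
    )
    birth = extract.patients.set_index("patient_id")["birth_date"].get(
        encounter["patient_id"], pd.NaT
    )

    note_pos = any(
        note_positive_for_splenomegaly(t, config) for t in notes["text"].fillna("")
    )
    path_pos = any(
        pathology_positive_for_hemophagocytosis(
            row["text"] or "",
            config,
            None if pd.isna(row["adjudicated_positive"]) else bool(row["adjudicated_positive"]),
        )
        for _, row in path.iterrows()
    )

    flags = {
        "fever": fever_met(temps, config),
        "splenomegaly": note_pos,
        "cytopenia": cytopenia_met(labs, birth, config),
        "tg_or_fibrinogen": tg_fib_met(labs, config),
        "hemophagocytosis": path_pos,
        "low_nk": nk_met(labs, config),
        "ferritin": ferritin_met(labs, config),
        "scd25": scd25_met(labs, config),
    }
    measured = {
        "fever": bool((temps["route"] == "oral").any()),
        "splenomegaly": len(notes) > 0,
        "cytopenia": _measured(labs, ["hemoglobin", "platelets", "neutrophils"]),
        "tg_or_fibrinogen": _measured(labs, ["triglycerides", "fibrinogen"]),
        "hemophagocytosis": len(path) > 0,
        "low_nk": _measured(labs, ["nk_activity"]),
        "ferritin": _measured(labs, ["ferritin"]),
        "scd25": _measured(labs, ["scd25"]),
    }
    return CriteriaProfile(
        encounter_id=eid,
        patient_id=encounter["patient_id"],
        flags=flags,
        measured=measured,
        count=sum(flags.values()),
    )


def evaluate_extract(extract: EhrExtract, config: StudyConfig) -> pd.DataFrame:
    """Criteria profiles for every encounter starting in the study window.

    Returns one row per encounter: the eight flags, the eight
    ``measured_*`` indicators, and ``count``; sorted by patient, start
    time, encounter id.  Row order of the input extract is irrelevant.
    """
    enc = extract.encounters
    start_days = enc["start"].dt.date
    in_window = enc[
        (start_days >= config.window_start) & (start_days <= config.window_end)
    ]

    # Pre-split the big tables once; per-encounter slicing dominates cost.
    by_enc = {
        "labs": dict(tuple(extract.labs.groupby("encounter_id", sort=False))),
        "temps": dict(tuple(extract.temperatures.groupby("encounter_id", sort=False))),
        "notes": dict(tuple(extract.notes.groupby("encounter_id", sort=False))),
        "path": dict(tuple(extract.pathology.groupby("encounter_id", sort=False))),
    }
    births = extract.patients.set_index("patient_id")["birth_date"]
    empty_labs = extract.labs.iloc[0:0]
    empty_temps = extract.temperatures.iloc[0:0]
    empty_notes = extract.notes.iloc[0:0]
    empty_path = extract.pathology.iloc[0:0]

    records = []
    for _, e in in_window.iterrows():
        eid = e["encounter_id"]
        window = episode_window(e, config)
        labs = _in_window(by_enc["labs"].get(eid, empty_labs), "collected_at", window)
        temps = _in_window(by_enc["temps"].get(eid, empty_temps), "taken_at", window)
        notes = _in_window(by_enc["notes"].get(eid, empty_notes), "authored_at", window)
        path = _in_window(by_enc["path"].get(eid, empty_path), "authored_at", window)
        birth = births.get(e["patient_id"], pd.NaT)

        flags = {
            "fever": fever_met(temps, config),
            "splenomegaly": any(
                note_positive_for_splenomegaly(t, config) for t in notes["text"].fillna("")
            ),
            "cytopenia": cytopenia_met(labs, birth, config),
            "tg_or_fibrinogen": tg_fib_met(labs, config),
            "hemophagocytosis": any(
                pathology_positive_for_hemophagocytosis(
                    row["text"] or "",
                    config,
                    None
                    if pd.isna(row["adjudicated_positive"])
                    else bool(row["adjudicated_positive"]),
                )
                for _, row in path.iterrows()
            ),
            "low_nk": nk_met(labs, config),
            "ferritin": ferritin_met(labs, config),
            "scd25": scd25_met(labs, config),
        }
        measured = {
            "fever": bool((temps["route"] == "oral").any()),
            "splenomegaly": len(notes) > 0,
            "cytopenia": _measured(labs, ["hemoglobin", "platelets", "neutrophils"]),
            "tg_or_fibrinogen": _measured(labs, ["triglycerides", "fibrinogen"]),
            "hemophagocytosis": len(path) > 0,
            "low_nk": _measured(labs, ["nk_activity"]),
            "ferritin": _measured(labs, ["ferritin"]),
            "scd25": _measured(labs, ["scd25"]),
        }
        rec = {
            "encounter_id": eid,
            "patient_id": e["patient_id"],
            "start": e["start"],
            **flags,
            **{f"measured_{k}": v for k, v in measured.items()},
            "count": sum(flags.values()),
        }
        records.append(rec)

    cols = (
        ["encounter_id", "patient_id", "start"]
        + list(CRITERIA)
        + [f"measured_{c}" for c in CRITERIA]
        + ["count"]
    )
    if not records:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame.from_records(records)[cols]
    return out.sort_values(
        ["patient_id", "start", "encounter_id"], kind="mergesort"
    ).reset_index(drop=True)
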