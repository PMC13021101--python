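"""The three HLH computable phenotypes and their overlap.

Three cohort definitions, each with a per-patient index (HLH-specific)
encounter:

1. **ICD cohort** — any in-window diagnosis event coded D76.1 or D76.2;
   index is the encounter tied to the first such code.
2. **Treatment-plan cohort** — any treatment plan or protocol whose name
   contains "HLH" or "h(a)emophagocytosis" (case-insensitive substring);
   index is the encounter of the first application.
3. **Criteria cohort** — maximum per-encounter criteria count ≥ the
   configured requirement (default 5); index is the encounter with the
   maximum count, earliest start on ties.

Plus the exploratory ferritin+fever screening set: every in-window
encounter (not patient) meeting both the ferritin and fever criteria.
"""

from __future__ import annotations

import pandas as pd

from .config import StudyConfig
from .io import EhrExtract

__all__ = [
    "build_icd_cohort",
    "build_plan_cohort",
    "build_criteria_cohort",
    "build_phenotypes",
    "compute_overlap",
    "build_screening_cohort",
]

OVERLAP_REGIONS = (
    "icd_only",
    "plan_only",
    "criteria_only",
    "icd_plan",
    "icd_criteria",
    "plan_criteria",
    "all_three",
)


def _resolve_encounter(
    extract: EhrExtract, patient_id: str, event_time: pd.Timestamp,
    linked_encounter: str | None, config: StudyConfig,
) -> str | None:
    """Index encounter for a diagnosis/plan event.

    Preference order: the explicitly linked encounter; else the patient's
    in-window encounter containing the event timestamp; else the nearest
    subsequent in-window encounter; else none.
    """
    if linked_encounter is not None and not pd.isna(linked_encounter):
        return linked_encounter
    enc = extract.encounters
    mine = enc[enc["patient_id"] == patient_id]
    days = mine["start"].dt.date
    mine = mine[(days >= config.window_start) & (days <= config.window_end)]
    if mine.empty:
        return None
    end = mine["end"].fillna(pd.Timestamp(config.window_end) + pd.Timedelta(days=1))
    containing = mine[(mine["start"] <= event_time) & (event_time <= end)]
    if not containing.empty:
        containing = containing.sort_values(["start", "encounter_id"], kind="mergesort")
        return containing.iloc[0]["encounter_id"]
    later = mine[mine["start"] >= event_time].sort_values(
        ["start", "encounter_id"], kind="mergesort"
    )
    if not later.empty:
        return later.iloc[0]["encounter_id"]
    return None


def build_icd_cohort(extract: EhrExtract, config: StudyConfig) -> pd.DataFrame:
    """Patients with an in-window HLH ICD-10 code and their first event.

    Codes match exactly (upper-cased, trimmed) against the configured
    list; child codes do not match.  Returns one row per member:
    ``patient_id``, ``first_code_at``, ``index_encounter`` (may be null
    when the event links to no encounter).
    """
    d = extract.diagnoses.copy()
    if d.empty:
        return pd.DataFrame(columns=["patient_id", "first_code_at", "index_encounter"])
    codes = d["icd10_code"].astype(str).str.strip().str.upper()
    days = d["noted_at"].dt.date
    hit = d[
        codes.isin([c.upper() for c in config.hlh_icd_codes])
        & (days >= config.window_start)
        & (days <= config.window_end)
    ]
    hit = hit.sort_values(["patient_id", "noted_at"], kind="mergesort")
    first = hit.groupby("patient_id", sort=True).first().reset_index()
    first["index_encounter"] = [
        _resolve_encounter(extract, r["patient_id"], r["noted_at"], r["encounter_id"], config)
        for _, r in first.iterrows()
    ]
    return first.rename(columns={"noted_at": "first_code_at"})[
        ["patient_id", "first_code_at", "index_encounter"]
    ]


def build_plan_cohort(extract: EhrExtract, config: StudyConfig) -> pd.DataFrame:
    """Patients with an HLH-named treatment plan and their first application."""
    tp = extract.treatment_plans
    if tp.empty:
        return pd.DataFrame(columns=["patient_id", "first_plan_at", "index_encounter"])
    pats = [p.lower() for p in config.plan_name_patterns]

    def _matches(row) -> bool:
        for field in ("display_name", "protocol_name"):
            v = row[field]
            if v is not None and not pd.isna(v) and any(p in str(v).lower() for p in pats):
                return True
        return False

    days = tp["applied_at"].dt.date
    in_win = tp[(days >= config.window_start) & (days <= config.window_end)]
    hit = in_win[in_win.apply(_matches, axis=1)] if not in_win.empty else in_win
    hit = hit.sort_values(["patient_id", "applied_at"], kind="mergesort")
    first = hit.groupby("patient_id", sort=True).first().reset_index()
    first["index_encounter"] = [
        _resolve_encounter(extract, r["patient_id"], r["applied_at"], r["encounter_id"], config)
        for _, r in first.iterrows()
    ]
    return first.rename(columns={"applied_at": "first_plan_at"})[
        ["patient_id", "first_plan_at", "index_encounter"]
    ]


def build_criteria_cohort(profiles: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-patient index encounter and membership from criteria profiles.

    Index = the encounter with the maximum criteria count; among equals,
    the earliest start, then lexicographic encounter id.  Membership
    requires ``max_criteria_count >= criteria_required``.  Patients with
    zero in-window encounters are absent from the result.
    """
    cols = ["patient_id", "index_encounter", "max_criteria_count", "member"]
    if profiles.empty:
        return pd.DataFrame(columns=cols)
    p = profiles.sort_values(
        ["patient_id", "count", "start", "encounter_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    first = p.groupby("patient_id", sort=True).first().reset_index()
    out = first.rename(columns={"encounter_id": "index_encounter", "count": "max_criteria_count"})
    out["member"] = out["max_criteria_count"] >= config.thresholds.criteria_required
    return out[cols]


def build_phenotypes(
    extract: EhrExtract, profiles: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Combine the three cohorts into one assignment table.

    One row per patient appearing in any cohort (plus criteria-profile
    patients, so ``max_criteria_count`` is recorded even for
    non-members): membership flags, the three index encounters, and the
    maximum criteria count.
    """
    icd = build_icd_cohort(extract, config).set_index("patient_id")
    plan = build_plan_cohort(extract, config).set_index("patient_id")
    crit = build_criteria_cohort(profiles, config).set_index("patient_id")

    ids = sorted(set(icd.index) | set(plan.index) | set(crit.index))
    rows = []
    for pid in ids:
        crow = crit.loc[pid] if pid in crit.index else None
        rows.append(
            {
                "patient_id": pid,
                "in_icd_cohort": pid in icd.index,
                "in_plan_cohort": pid in plan.index,
                "in_criteria_cohort": bool(crow["member"]) if crow is not None else False,
                "index_encounter_icd": icd.loc[pid, "index_encounter"] if pid in icd.index else None,
                "index_encounter_plan": plan.loc[pid, "index_encounter"] if pid in plan.index else None,
                "index_encounter_criteria": crow["index_encounter"] if crow is not None else None,
                "max_criteria_count": int(crow["max_criteria_count"]) if crow is not None else 0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "in_icd_cohort",
            "in_plan_cohort",
            "in_criteria_cohort",
            "index_encounter_icd",
            "index_encounter_plan",
            "index_encounter_criteria",
            "max_criteria_count",
        ],
    )


def compute_overlap(assignments: pd.DataFrame) -> dict:
    """Counts of the seven regions of the three-cohort Venn diagram.

    Patients outside all three cohorts do not contribute; ``union`` is
    the number of patients in at least one cohort and always equals the
    sum of the seven region counts.
    """
    counts = dict.fromkeys(OVERLAP_REGIONS, 0)
    for _, r in assignments.iterrows():
        key = (bool(r["in_icd_cohort"]), bool(r["in_plan_cohort"]), bool(r["in_criteria_cohort"]))
        region = {
            (True, False, False): "icd_only",
            (False, True, False): "plan_only",
            (False, False, True): "criteria_only",
            (True, True, False): "icd_plan",
            (True, False, True): "icd_criteria",
            (False, True, True): "plan_criteria",
            (True, True, True): "all_three",
        }.get(key)
        if region is not None:
            counts[region] += 1
    counts["union"] = sum(counts[r] for r in OVERLAP_REGIONS)
    counts["n_icd"] = counts["icd_only"] + counts["icd_plan"] + counts["icd_criteria"] + counts["all_three"]
    counts["n_plan"] = counts["plan_only"] + counts["icd_plan"] + counts["plan_criteria"] + counts["all_three"]
    counts["n_criteria"] = (
        counts["criteria_only"] + counts["icd_criteria"] + counts["plan_criteria"] + counts["all_three"]
    )
    return counts


def build_screening_cohort(profiles: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Encounter-level ferritin+fever screening set.

    Every in-window encounter where both the ferritin and fever criteria
    are met — multiple episodes per patient are kept — with the full
    criteria profile and ``meets_threshold`` (count ≥ requirement).
    """
    if profiles.empty:
        return profiles.assign(meets_threshold=pd.Series(dtype=bool))
    hit = profiles[profiles["ferritin"] & profiles["fever"]].copy()
    hit["meets_threshold"] = hit["count"] >= config.thresholds.criteria_required
    return hit.reset_index(drop=True)
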