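"""Therapy exposure, clinical outcomes, and the stratified comparison.

Therapy exposure is classified two ways, each both encounter-scoped
(during the patient's HLH-specific encounter) and globally (any
encounter): receipt of any chemotherapy, and receipt of any HLH-directed
drug (dexamethasone, methylprednisolone, anakinra, ruxolitinib,
cyclosporine, etoposide, or emapalumab, at any dose).  The treated-vs-
untreated comparison splits the ≥5-criteria cohort by HLH-directed
therapy during the index encounter and reproduces the descriptive table:
demographics, admission diagnoses, ICD coding and its timing, the eight
criteria, consulting services, length of stay, ICU admission,
in-hospital and 30-day mortality, and post-encounter stem-cell
transplant, with rank-sum / chi-square / Fisher tests, Wald risk
differences, and a bootstrap CI on the median length-of-stay difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .criteria import CRITERIA, episode_window
from .io import EhrExtract, SERVICES
from .stats import RiskDifference, median_difference, risk_difference, two_group_test

__all__ = [
    "classify_therapy",
    "derive_outcomes",
    "compare_groups",
    "screening_summary",
    "make_table1",
    "ComparisonReport",
    "ScreeningSummary",
    "AGE_GROUPS",
]

AGE_GROUPS = ("0-<1", "1-4", "5-14", ">=15")


def _age_group(birth_date, at) -> str:
    years = (pd.Timestamp(at) - pd.Timestamp(birth_date)).days / 365.25
    if years < 1:
        return "0-<1"
    if years < 5:
        return "1-4"
    if years < 15:
        return "5-14"
    return ">=15"


def classify_therapy(
    extract: EhrExtract,
    index_encounters: pd.Series | dict,
    config: StudyConfig,
) -> pd.DataFrame:
    """Per-patient therapy exposure relative to an index encounter.

    ``index_encounters`` maps patient id → index encounter id (null
    allowed: encounter-scoped flags are then false).  Encounter scope
    means administration within the index episode window.  The therapy
    pattern is classified from the HLH-directed drugs received during
    the index encounter when any, otherwise from any encounter:
    ``steroid_only`` (only dexamethasone/methylprednisolone),
    ``steroid_plus_other``, ``other_only``, or ``none``.
    """
    if isinstance(index_encounters, dict):
        index_encounters = pd.Series(index_encounters, dtype="object")
    exposure_cols = [
        "patient_id", "chemo_index_encounter", "chemo_any_encounter",
        "hlh_directed_index_encounter", "hlh_directed_any_encounter",
        "chemo_or_hlh_index", "chemo_or_hlh_any", "therapy_pattern",
    ]
    if len(index_encounters) == 0:
        return pd.DataFrame(columns=exposure_cols)
    meds = extract.medications
    enc = extract.encounters.set_index("encounter_id")
    hlh_drugs = {d.lower() for d in config.hlh_directed_drugs}
    steroids = {d.lower() for d in config.steroid_drugs}

    names = meds["generic_name"].astype(str).str.lower()
    is_hlh = names.isin(hlh_drugs)
    is_chemo = meds["is_chemotherapy"].fillna(False).astype(bool)

    rows = []
    by_pat = dict(tuple(meds.assign(_hlh=is_hlh, _chemo=is_chemo, _name=names).groupby("patient_id", sort=False)))
    for pid, index_eid in index_encounters.items():
        mine = by_pat.get(pid)
        if mine is None:
            rows.append(
                dict(patient_id=pid, chemo_index_encounter=False, chemo_any_encounter=False,
                     hlh_directed_index_encounter=False, hlh_directed_any_encounter=False,
                     chemo_or_hlh_index=False, chemo_or_hlh_any=False, therapy_pattern="none")
            )
            continue
        chemo_any = bool(mine["_chemo"].any())
        hlh_any = bool(mine["_hlh"].any())
        chemo_idx = hlh_idx = False
        idx_drugs: set[str] = set()
        if index_eid is not None and not pd.isna(index_eid) and index_eid in enc.index:
            lo, hi = episode_window(enc.loc[index_eid], config)
            scoped = mine[(mine["administered_at"] >= lo) & (mine["administered_at"] <= hi)]
            chemo_idx = bool(scoped["_chemo"].any())
            hlh_idx = bool(scoped["_hlh"].any())
            idx_drugs = set(scoped.loc[scoped["_hlh"], "_name"])
        basis = idx_drugs if idx_drugs else set(mine.loc[mine["_hlh"], "_name"])
        if not basis:
            pattern = "none"
        elif basis <= steroids:
            pattern = "steroid_only"
        elif basis & steroids:
            pattern = "steroid_plus_other"
        else:
            pattern = "other_only"
        rows.append(
            dict(patient_id=pid, chemo_index_encounter=chemo_idx, chemo_any_encounter=chemo_any,
                 hlh_directed_index_encounter=hlh_idx, hlh_directed_any_encounter=hlh_any,
                 chemo_or_hlh_index=chemo_idx or hlh_idx, chemo_or_hlh_any=chemo_any or hlh_any,
                 therapy_pattern=pattern)
        )
    return pd.DataFrame(rows, columns=exposure_cols)


def derive_outcomes(
    extract: EhrExtract, assignments: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Outcome record per criteria-cohort member, anchored at the index
    encounter.

    The 30-day mortality window is anchored at the index encounter start
    date, inclusive of day 30.  In-hospital death means a death date
    inside the encounter interval or a discharge flagged not-alive.
    ICD timing compares the patient's first in-window HLH code date with
    the index interval.
    """
    members = assignments[assignments["in_criteria_cohort"]]
    enc = extract.encounters.set_index("encounter_id")
    pat = extract.patients.set_index("patient_id")
    hlh_codes = [c.upper() for c in config.hlh_icd_codes]
    d = extract.diagnoses
    codes = d["icd10_code"].astype(str).str.strip().str.upper()
    days = d["noted_at"].dt.date
    hlh_dx = d[codes.isin(hlh_codes) & (days >= config.window_start) & (days <= config.window_end)]
    first_code = hlh_dx.sort_values("noted_at").groupby("patient_id")["noted_at"].first()

    svc = extract.services
    icu = extract.icu
    sct = extract.sct

    rows = []
    for _, a in members.iterrows():
        pid = a["patient_id"]
        eid = a["index_encounter_criteria"]
        if eid is None or pd.isna(eid) or eid not in enc.index:
            raise ValueError(f"criteria-cohort patient {pid} has no index encounter")
        e = enc.loc[eid]
        lo, hi = episode_window(e, config)
        start, end = pd.Timestamp(e["start"]), hi
        los_days = (end - start) / pd.Timedelta(days=1)
        death = pat.loc[pid, "death_date"] if pid in pat.index else pd.NaT
        discharged_alive = e.get("discharged_alive")
        in_hosp = False
        death30 = False
        if not pd.isna(death):
            in_hosp = bool(start.normalize() <= death <= end)
            death30 = bool(
                start.normalize()
                <= death
                <= start.normalize() + pd.Timedelta(days=config.mortality_window_days)
            )
        if discharged_alive is not None and discharged_alive is not pd.NA and not pd.isna(discharged_alive):
            in_hosp = in_hosp or (not bool(discharged_alive))
        first = first_code.get(pid, pd.NaT)
        if pd.isna(first):
            icd_timing = "never"
        elif first < start.normalize():
            icd_timing = "before"
        elif first <= end:
            icd_timing = "during"
        else:
            icd_timing = "after"
        my_sct = sct[sct["patient_id"] == pid]
        sct_after = bool((my_sct["date"] > start).any()) if not my_sct.empty else False
        my_services = set(svc.loc[svc["encounter_id"] == eid, "service"])
        birth = pat.loc[pid, "birth_date"]
        rows.append(
            dict(
                patient_id=pid,
                index_encounter=eid,
                los_days=float(los_days),
                icu=bool((icu["encounter_id"] == eid).any()),
                in_hospital_death=in_hosp,
                death_within_30d=death30,
                sct_after=sct_after,
                services=my_services,
                age_group=_age_group(birth, start),
                admission_dx=e.get("admission_diagnosis"),
                icd_timing=icd_timing,
                sex=pat.loc[pid, "sex"],
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Treated-vs-untreated comparison over the ≥criteria cohort."""

    n_treated: int
    n_untreated: int
    rows: pd.DataFrame
    in_hospital_rd: RiskDifference | None
    mortality30_rd: RiskDifference | None
    los: dict
    top5_admission_dx: list = field(default_factory=list)


def _cat_row(section, variable, x1, n1, x2, n2, test=True):
    if test and n1 > 0 and n2 > 0:
        stat, p, name = two_group_test(
            "categorical", [[x1, x2], [n1 - x1, n2 - x2]]
        )
    else:
        stat, p, name = float("nan"), float("nan"), "not-applicable"
    return dict(
        section=section, variable=variable,
        treated_n=x1, treated_pct=round(100 * x1 / n1, 1) if n1 else float("nan"),
        untreated_n=x2, untreated_pct=round(100 * x2 / n2, 1) if n2 else float("nan"),
        statistic=stat, p=p, test=name,
    )


def compare_groups(
    extract: EhrExtract,
    profiles: pd.DataFrame,
    assignments: pd.DataFrame,
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: StudyConfig,
    seed: int = 0,
) -> ComparisonReport:
    """Compare criteria-cohort patients by HLH-directed therapy receipt.

    Groups are defined by HLH-directed therapy during the index
    encounter.  Emits one row per table line (counts, one-decimal
    percentages, test, p), the two mortality risk differences, and the
    median length-of-stay difference with a seeded bootstrap CI.  The
    sCD25 and NK-activity rows carry both cohort-N and measured-N
    denominators.  If either group is empty, tests are suppressed.
    """
    members = assignments[assignments["in_criteria_cohort"]][
        ["patient_id", "index_encounter_criteria"]
    ]
    df = members.merge(exposures, on="patient_id").merge(outcomes, on="patient_id")
    prof_by_enc = profiles.set_index("encounter_id")
    df = df.join(
        prof_by_enc[list(CRITERIA) + [f"measured_{c}" for c in CRITERIA]],
        on="index_encounter_criteria",
    )
    treated = df[df["hlh_directed_index_encounter"]]
    untreated = df[~df["hlh_directed_index_encounter"]]
    n1, n2 = len(treated), len(untreated)
    testable = n1 > 0 and n2 > 0
    rows = []

    # Demographics.
    rows.append(_cat_row("demographics", "male_sex",
                         int((treated["sex"] == "male").sum()), n1,
                         int((untreated["sex"] == "male").sum()), n2, testable))
    age_table = [
        [int((treated["age_group"] == g).sum()), int((untreated["age_group"] == g).sum())]
        for g in AGE_GROUPS
    ]
    stat, p, name = (
        two_group_test("categorical", age_table) if testable
        else (float("nan"), float("nan"), "not-applicable")
    )
    rows.append(dict(section="demographics", variable="age_group",
                     treated_n=n1, treated_pct=100.0, untreated_n=n2,
                     untreated_pct=100.0, statistic=stat, p=p, test=name))
    for g, (a, b) in zip(AGE_GROUPS, age_table):
        rows.append(dict(section="demographics", variable=f"age_{g}",
                         treated_n=a, treated_pct=round(100 * a / n1, 1) if n1 else float("nan"),
                         untreated_n=b, untreated_pct=round(100 * b / n2, 1) if n2 else float("nan"),
                         statistic=float("nan"), p=float("nan"), test=""))

    # Top-5 admission diagnoses over the whole cohort, ties lexical.
    dx_counts = (
        df["admission_dx"].dropna().value_counts().rename_axis("dx").reset_index(name="n")
    )
    dx_counts = dx_counts.sort_values(["n", "dx"], ascending=[False, True], kind="mergesort")
    top5 = dx_counts["dx"].head(5).tolist()
    for dx in top5:
        rows.append(_cat_row("admission_diagnosis", dx,
                             int((treated["admission_dx"] == dx).sum()), n1,
                             int((untreated["admission_dx"] == dx).sum()), n2, testable))

    # ICD diagnosis and its timing.
    icd_any_t = int((treated["icd_timing"] != "never").sum())
    icd_any_u = int((untreated["icd_timing"] != "never").sum())
    rows.append(_cat_row("icd", "icd_hlh_diagnosis", icd_any_t, n1, icd_any_u, n2, testable))
    timing_levels = ("before", "during", "after", "never")
    timing_table = [
        [int((treated["icd_timing"] == lv).sum()), int((untreated["icd_timing"] == lv).sum())]
        for lv in timing_levels
    ]
    stat, p, name = (
        two_group_test("categorical", timing_table) if testable
        else (float("nan"), float("nan"), "not-applicable")
    )
    rows.append(dict(section="icd", variable="icd_timing", treated_n=n1, treated_pct=100.0,
                     untreated_n=n2, untreated_pct=100.0, statistic=stat, p=p, test=name))
    for lv, (a, b) in zip(timing_levels, timing_table):
        rows.append(dict(section="icd", variable=f"icd_timing_{lv}",
                         treated_n=a, treated_pct=round(100 * a / n1, 1) if n1 else float("nan"),
                         untreated_n=b, untreated_pct=round(100 * b / n2, 1) if n2 else float("nan"),
                         statistic=float("nan"), p=float("nan"), test=""))

    # The eight criteria at the index encounter.
    for c in CRITERIA:
        r = _cat_row("criteria", c, int(treated[c].sum()), n1, int(untreated[c].sum()), n2, testable)
        r["treated_measured_n"] = int(treated[f"measured_{c}"].sum())
        r["untreated_measured_n"] = int(untreated[f"measured_{c}"].sum())
        r["treated_pct_of_measured"] = (
            round(100 * int(treated[c].sum()) / r["treated_measured_n"], 1)
            if r["treated_measured_n"] else float("nan")
        )
        r["untreated_pct_of_measured"] = (
            round(100 * int(untreated[c].sum()) / r["untreated_measured_n"], 1)
            if r["untreated_measured_n"] else float("nan")
        )
        rows.append(r)

    # Services involved.
    for s in SERVICES:
        rows.append(_cat_row("services", s,
                             int(treated["services"].apply(lambda x: s in x).sum()), n1,
                             int(untreated["services"].apply(lambda x: s in x).sum()), n2,
                             testable))

    # Clinical outcomes.
    for var, col in [("icu", "icu"), ("in_hospital_death", "in_hospital_death"),
                     ("death_within_30d", "death_within_30d"), ("sct_after", "sct_after")]:
        rows.append(_cat_row("outcomes", var,
                             int(treated[col].sum()), n1, int(untreated[col].sum()), n2, testable))

    los: dict = {}
    in_hosp_rd = d30_rd = None
    if testable:
        l1 = treated["los_days"].to_numpy()
        l2 = untreated["los_days"].to_numpy()
        diff, ci = median_difference(l1, l2, seed=seed)
        _, p_los, _ = two_group_test("continuous", l1, l2)
        los = dict(
            median_treated=float(np.median(l1)),
            median_untreated=float(np.median(l2)),
            iqr_treated=(float(np.percentile(l1, 25)), float(np.percentile(l1, 75))),
            iqr_untreated=(float(np.percentile(l2, 25)), float(np.percentile(l2, 75))),
            median_difference=diff, ci_low=ci[0], ci_high=ci[1], p=p_los,
        )
        in_hosp_rd = risk_difference(
            int(treated["in_hospital_death"].sum()), n1,
            int(untreated["in_hospital_death"].sum()), n2,
        )
        d30_rd = risk_difference(
            int(treated["death_within_30d"].sum()), n1,
            int(untreated["death_within_30d"].sum()), n2,
        )
    return ComparisonReport(
        n_treated=n1, n_untreated=n2, rows=pd.DataFrame(rows),
        in_hospital_rd=in_hosp_rd, mortality30_rd=d30_rd, los=los,
        top5_admission_dx=top5,
    )


SCREENING_CRITERIA = (
    "cytopenia",
    "tg_or_fibrinogen",
    "splenomegaly",
    "scd25",
    "hemophagocytosis",
    "low_nk",
)


@dataclass
class ScreeningSummary:
    """Distribution of the remaining criteria among ferritin+fever encounters."""

    total_encounters: int
    n_meeting: int          # encounters at or above the criteria requirement
    n_below: int
    share_meeting_pct: float
    number_needed_to_screen: float  # nan when no encounter meets threshold
    table: pd.DataFrame     # criterion x {all, meeting, below} counts and pct


def screening_summary(screening: pd.DataFrame) -> ScreeningSummary:
    """Summarize a ferritin+fever screening set by criteria threshold.

    For each remaining criterion: count and percentage among all
    encounters, among those meeting the threshold, and among those
    below.  Also the threshold-stratum share of all encounters and the
    number needed to screen, ``round(total / meeting)``.
    """
    total = len(screening)
    meeting = screening[screening["meets_threshold"]] if total else screening
    below = screening[~screening["meets_threshold"]] if total else screening
    n_meet, n_below = len(meeting), len(below)
    recs = []
    for c in SCREENING_CRITERIA:
        row = {"criterion": c}
        for label, sub in (("all", screening), ("meeting", meeting), ("below", below)):
            n = int(sub[c].sum()) if len(sub) else 0
            row[f"{label}_n"] = n
            row[f"{label}_pct"] = round(100 * n / len(sub), 1) if len(sub) else 0.0
            mcol = f"measured_{c}"
            row[f"{label}_measured_n"] = int(sub[mcol].sum()) if len(sub) and mcol in sub else 0
        recs.append(row)
    share = round(100 * n_meet / total, 1) if total else 0.0
    nns = float(math.floor(total / n_meet + 0.5)) if n_meet else float("nan")
    return ScreeningSummary(
        total_encounters=total, n_meeting=n_meet, n_below=n_below,
        share_meeting_pct=share, number_needed_to_screen=nns,
        table=pd.DataFrame(recs),
    )


def make_table1(
    extract: EhrExtract, assignments: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """Therapy-receipt counts per cohort (the three-column summary).

    For each cohort, exposure is computed relative to that cohort's own
    index encounters; rows are monotone (index ⊆ any ⊆ chemo-or-HLH).
    """
    cols = {}
    specs = [
        ("icd", "in_icd_cohort", "index_encounter_icd"),
        ("plan", "in_plan_cohort", "index_encounter_plan"),
        ("criteria", "in_criteria_cohort", "index_encounter_criteria"),
    ]
    for name, flag, idx_col in specs:
        members = assignments[assignments[flag]]
        idx = pd.Series(members[idx_col].values, index=members["patient_id"].values)
        exp = classify_therapy(extract, idx, config)
        cols[name] = {
            "total_patients": len(members),
            "chemo_index_encounter": int(exp["chemo_index_encounter"].sum()),
            "chemo_any_encounter": int(exp["chemo_any_encounter"].sum()),
            "chemo_or_hlh_index_encounter": int(exp["chemo_or_hlh_index"].sum()),
            "chemo_or_hlh_any_encounter": int(exp["chemo_or_hlh_any"].sum()),
            "hlh_directed_index_encounter": int(exp["hlh_directed_index_encounter"].sum()),
            "hlh_directed_any_encounter": int(exp["hlh_directed_any_encounter"].sum()),
        }
    return pd.DataFrame(cols)
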