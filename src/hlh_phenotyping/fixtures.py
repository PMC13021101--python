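"""Deterministic fixture extracts with prescribed contingency structure.

These build small synthetic extracts by direct placement (no sampling)
whose group sizes and event counts equal published-style summary counts,
so the whole pipeline — criteria engine, cohort builder, therapy
classification, comparison statistics — can be exercised end-to-end
against known totals:

* :func:`table2_fixture` — 245 patients meeting ≥5 criteria, split
  193 treated / 52 untreated by HLH-directed therapy at the index
  encounter, with fixed per-group counts for every comparison row
  (mortality, LOS medians, services, criteria, ICD timing, ...).
* :func:`table3_fixture` — 1325 ferritin+fever screening encounters, 252
  of which meet ≥5 criteria, with fixed per-criterion counts per
  stratum.

Flag matrices with exact column sums under row-sum bounds are
constructed with a Gale–Ryser style greedy allocator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import EhrExtract, empty_extract
from .synthetic import _Builder

__all__ = ["allocate_flags", "table2_fixture", "table3_fixture"]

CRIT_ORDER = (
    "fever",
    "splenomegaly",
    "cytopenia",
    "tg_or_fibrinogen",
    "hemophagocytosis",
    "low_nk",
    "ferritin",
    "scd25",
)


def allocate_flags(
    n_rows: int, col_targets: dict[str, int], row_min: int, row_max: int
) -> pd.DataFrame:
    """Boolean matrix with exact column sums and row sums in bounds.

    Row totals are fixed first (``row_min`` everywhere, surplus spread
    one per row from the top), then each column — largest target first —
    is assigned to the rows with the greatest unmet row total (ties by
    row index).  Raises if the requested degree sequence is infeasible.
    """
    total = sum(col_targets.values())
    if not n_rows * row_min <= total <= n_rows * row_max:
        raise ValueError("column totals incompatible with row bounds")
    need = np.full(n_rows, row_min, dtype=int)
    extra = total - n_rows * row_min
    need[: extra % n_rows] += extra // n_rows + 1
    need[extra % n_rows:] += extra // n_rows
    if need.max() > row_max:
        raise ValueError("row bounds violated")

    out = pd.DataFrame(False, index=range(n_rows), columns=list(col_targets))
    remaining = need.copy()
    for col in sorted(col_targets, key=lambda c: -col_targets[c]):
        k = col_targets[col]
        if k > n_rows:
            raise ValueError(f"column {col} target exceeds row count")
        order = np.lexsort((np.arange(n_rows), -remaining))
        chosen = order[:k]
        if k and remaining[chosen[-1]] <= 0:
            raise ValueError("infeasible flag allocation")
        out.iloc[chosen, out.columns.get_loc(col)] = True
        remaining[chosen] -= 1
    if remaining.any():
        raise ValueError("flag allocation left unmet row totals")
    return out


def _realize_flags(b: _Builder, pid, eid, start, flags, *,
                   scd25_measured=False, nk_measured=False):
    """Place raw rows so the criteria engine reproduces ``flags`` exactly."""
    t = start + pd.Timedelta(hours=2)

    def lab(analyte, value):
        b.add("labs", patient_id=pid, encounter_id=eid, analyte=analyte,
              value=float(value), collected_at=t)

    b.add("temperatures", patient_id=pid, encounter_id=eid, taken_at=t,
          temperature_c=38.5 if flags["fever"] else 37.0, route="oral")
    lab("ferritin", 1200.0 if flags["ferritin"] else 100.0)
    if flags["cytopenia"]:
        lab("hemoglobin", 75.0), lab("platelets", 50.0), lab("neutrophils", 3.0)
    else:
        lab("hemoglobin", 120.0), lab("platelets", 200.0), lab("neutrophils", 3.0)
    lab("triglycerides", 3.5 if flags["tg_or_fibrinogen"] else 1.5)
    if flags["scd25"]:
        lab("scd25", 3000.0)
    elif scd25_measured:
        lab("scd25", 800.0)
    if flags["low_nk"]:
        lab("nk_activity", 1.0)
    elif nk_measured:
        lab("nk_activity", 0.0)
    b.add("notes", patient_id=pid, encounter_id=eid, authored_at=t,
          text="Ultrasound demonstrates splenomegaly." if flags["splenomegaly"]
          else "Abdomen soft, no splenomegaly appreciated.")
    if flags["hemophagocytosis"]:
        b.add("pathology", patient_id=pid, encounter_id=eid, authored_at=t,
              text="Bone marrow aspirate demonstrates hemophagocytosis.",
              adjudicated_positive=None)


# Per-group column targets for the treated/untreated comparison fixture.
_T2 = {
    "n": (193, 52),
    "criteria": {
        "ferritin": (190, 52), "fever": (177, 47), "cytopenia": (176, 48),
        "tg_or_fibrinogen": (183, 47), "splenomegaly": (175, 46),
        "scd25": (91, 26), "hemophagocytosis": (33, 3), "low_nk": (13, 1),
    },
    "scd25_measured": (135, 36),
    "nk_measured": (53, 7),
    "male": (96, 27),
    # The published untreated age-group counts (13, 12, 14, 12) sum to 51,
    # one short of n=52; the extra patient is placed in the 5-14 stratum.
    "age_groups": ((43, 44, 65, 41), (13, 12, 15, 12)),
    "admission_dx": {
        "Fever": (37, 14), "Sepsis": (9, 7), "Leukemia": (12, 2),
        "Acute lymphoblastic leukemia": (8, 4), "Neutropenia": (6, 3),
    },
    "icd_timing": {"before": (8, 0), "during": (55, 3), "after": (9, 2)},
    "services": {
        "oncology": (109, 22), "hematology": (103, 33), "rheumatology": (89, 16),
        "infectious diseases": (159, 45), "immunology": (46, 13), "neurology": (69, 17),
    },
    "icu": (111, 22),
    "in_hospital_death": (29, 7),
    "death_30d": (32, 8),
    "sct": (13, 1),
    "steroid_only": 131,
    "steroid_plus_other": 56,
    "chemo_index": (73, 5),
}

_AGE_DELTAS_DAYS = (183, 2 * 365, 8 * 365, 20 * 365)


def _treated_los() -> np.ndarray:
    los = np.empty(193)
    los[0:29] = 5 + 0.5 * np.arange(29)          # in-hospital deaths
    los[29:32] = 10.0                            # post-discharge 30-day deaths
    los[32:96] = 20 + 0.2 * np.arange(64)        # below-median block
    los[96] = 33.4                               # the median
    los[97:193] = 35 + np.arange(96)             # above-median block
    return los


def _untreated_los() -> np.ndarray:
    los = np.empty(52)
    los[0:7] = 5 + np.arange(7)
    los[7] = 9.0
    los[8:25] = 12 + 0.4 * np.arange(17)
    los[25:27] = 20.8
    los[27:52] = 25 + np.arange(25)
    return los


def table2_fixture() -> EhrExtract:
    """245-patient extract reproducing the treated-vs-untreated table.

    Every patient has one ≥5-criteria inpatient index encounter; the
    treated group is defined by HLH-directed drug administration during
    it.  A handful of second encounters carry the any-encounter
    chemotherapy/therapy counts.
    """
    b = _Builder()
    groups = [
        ("t", 0, 193, _treated_los()),
        ("u", 1, 52, _untreated_los()),
    ]
    flag_mats = {}
    for prefix, g, n, _ in groups:
        targets = {c: _T2["criteria"][c][g] for c in _T2["criteria"]}
        flag_mats[prefix] = allocate_flags(n, targets, row_min=5, row_max=8)

    for prefix, g, n, los in groups:
        flags_df = flag_mats[prefix]
        # Extra measured-but-normal sCD25 / NK assays beyond the positives.
        scd_needed = _T2["scd25_measured"][g] - _T2["criteria"]["scd25"][g]
        nk_needed = _T2["nk_measured"][g] - _T2["criteria"]["low_nk"][g]
        scd_extra = [i for i in range(n) if not flags_df.loc[i, "scd25"]][:scd_needed]
        nk_extra = [i for i in range(n) if not flags_df.loc[i, "low_nk"]][:nk_needed]

        age_bounds = np.cumsum(_T2["age_groups"][g])
        dx_labels = []
        for dx, counts in _T2["admission_dx"].items():
            dx_labels += [dx] * counts[g]
        dx_labels += [f"Other diagnosis {prefix}{i:03d}" for i in range(n - len(dx_labels))]
        timing = (
            ["before"] * _T2["icd_timing"]["before"][g]
            + ["during"] * _T2["icd_timing"]["during"][g]
            + ["after"] * _T2["icd_timing"]["after"][g]
        )

        for i in range(n):
            pid = f"{prefix}{i + 1:03d}"
            eid = f"{pid}e1"
            start = pd.Timestamp("2019-01-01") + pd.Timedelta(days=2 * i + g)
            end = start + pd.Timedelta(days=float(los[i]))
            age_grp = int(np.searchsorted(age_bounds, i, side="right"))
            birth = (start - pd.Timedelta(days=_AGE_DELTAS_DAYS[age_grp])).normalize()

            in_hosp_death = i < _T2["in_hospital_death"][g]
            late_death = _T2["in_hospital_death"][g] <= i < _T2["death_30d"][g]
            death = None
            if in_hosp_death:
                death = (start + pd.Timedelta(days=float(los[i]))).normalize()
            elif late_death:
                death = (start + pd.Timedelta(days=25)).normalize()

            b.add("patients", patient_id=pid,
                  sex="male" if i < _T2["male"][g] else "female",
                  birth_date=birth, death_date=death)
            b.add("encounters", encounter_id=eid, patient_id=pid,
                  encounter_class="inpatient", start=start, end=end,
                  admission_diagnosis=dx_labels[i],
                  discharged_alive=not in_hosp_death)

            flags = flags_df.loc[i].to_dict()
            _realize_flags(b, pid, eid, start, flags,
                           scd25_measured=i in scd_extra, nk_measured=i in nk_extra)

            if i < len(timing):
                when = {"before": start - pd.Timedelta(days=10),
                        "during": start + pd.Timedelta(days=1),
                        "after": end + pd.Timedelta(days=10)}[timing[i]]
                b.add("diagnoses", patient_id=pid, icd10_code="D76.1",
                      noted_at=when,
                      encounter_id=eid if timing[i] == "during" else None)

            for svc, counts in _T2["services"].items():
                if i < counts[g]:
                    b.add("services", patient_id=pid, encounter_id=eid, service=svc)
            if i < _T2["icu"][g]:
                b.add("icu", patient_id=pid, encounter_id=eid,
                      start=start + pd.Timedelta(hours=1),
                      end=start + pd.Timedelta(hours=12))
            if i < _T2["sct"][g]:
                b.add("sct", patient_id=pid, date=(start + pd.Timedelta(days=60)).normalize())

            def med(name, chemo, enc=eid, at=start + pd.Timedelta(hours=5)):
                b.add("medications", patient_id=pid, encounter_id=enc,
                      generic_name=name, administered_at=at, is_chemotherapy=chemo)

            if prefix == "t":
                if i < _T2["steroid_only"]:
                    med("dexamethasone", False)
                elif i < _T2["steroid_only"] + _T2["steroid_plus_other"]:
                    med("dexamethasone", False)
                    med("anakinra", False)
                else:
                    med("anakinra", False)
                if i < _T2["chemo_index"][0]:
                    med("cytarabine", True)
            else:
                # Index-encounter chemotherapy without HLH-directed drugs.
                if 15 <= i <= 19:
                    med("cytarabine", True)

            # Second encounters carrying any-encounter exposure.
            second_drug = None
            if prefix == "t" and 73 <= i <= 93:
                second_drug = ("cytarabine", True)
            if prefix == "u" and i < 19:
                second_drug = ("dexamethasone", False)
            if second_drug is not None:
                e2 = f"{pid}e2"
                s2 = end + pd.Timedelta(days=40)
                b.add("encounters", encounter_id=e2, patient_id=pid,
                      encounter_class="inpatient", start=s2,
                      end=s2 + pd.Timedelta(days=2), admission_diagnosis=None,
                      discharged_alive=True)
                b.add("medications", patient_id=pid, encounter_id=e2,
                      generic_name=second_drug[0],
                      administered_at=s2 + pd.Timedelta(hours=5),
                      is_chemotherapy=second_drug[1])
    return b.extract()


# Screening-fixture column targets: counts among the ≥5 and <5 strata.
_T3 = {
    "n_meeting": 252,
    "n_below": 1073,
    "criteria": {
        "cytopenia": (231, 475), "tg_or_fibrinogen": (230, 255),
        "splenomegaly": (229, 290), "scd25": (114, 45),
        "hemophagocytosis": (27, 0), "low_nk": (11, 1),
    },
    "scd25_measured": (172, 165),
    "nk_measured": (55, 24),
}


def table3_fixture() -> EhrExtract:
    """1325 ferritin+fever encounters with fixed criterion distributions."""
    b = _Builder()
    strata = [
        ("a", 0, _T3["n_meeting"], 3, 6),   # >= 5 total criteria: 3-6 extras
        ("z", 1, _T3["n_below"], 0, 2),     # < 5: at most 2 extras
    ]
    for prefix, g, n, rmin, rmax in strata:
        targets = {c: _T3["criteria"][c][g] for c in _T3["criteria"]}
        flags_df = allocate_flags(n, targets, row_min=rmin, row_max=rmax)
        scd_needed = _T3["scd25_measured"][g] - targets["scd25"]
        nk_needed = _T3["nk_measured"][g] - targets["low_nk"]
        scd_extra = set([i for i in range(n) if not flags_df.loc[i, "scd25"]][:scd_needed])
        nk_extra = set([i for i in range(n) if not flags_df.loc[i, "low_nk"]][:nk_needed])
        for i in range(n):
            pid = f"q{prefix}{i + 1:04d}"
            eid = f"{pid}e1"
            start = pd.Timestamp("2019-01-01") + pd.Timedelta(days=i % 900, hours=8)
            b.add("patients", patient_id=pid, sex="female",
                  birth_date=(start - pd.Timedelta(days=5 * 365)).normalize(),
                  death_date=None)
            b.add("encounters", encounter_id=eid, patient_id=pid,
                  encounter_class="inpatient", start=start,
                  end=start + pd.Timedelta(days=5),
                  admission_diagnosis="Fever", discharged_alive=True)
            flags = {c: bool(flags_df.loc[i, c]) for c in _T3["criteria"]}
            flags["ferritin"] = True
            flags["fever"] = True
            _realize_flags(b, pid, eid, start, flags,
                           scd25_measured=i in scd_extra, nk_measured=i in nk_extra)
    return b.extract()
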