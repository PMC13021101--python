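"""EHR extract data model and delimited-text round-tripping.

An :class:`EhrExtract` is a bundle of typed pandas tables mirroring a
single institution's export: patients, encounters, laboratory results,
temperature observations, coded diagnoses, treatment plans, medication
administrations, clinical notes, pathology reports, ICU intervals,
consulting-service contacts and stem-cell-transplant events.  Each table
has a fixed schema (column names, dtypes, enumerated codes) and a set of
row-level invariants; :func:`load_extract` validates them all and reports
every violation with its table and row index.

Canonical units are fixed per analyte (ferritin µg/L, hemoglobin g/L,
platelets and neutrophils 10⁹/L, triglycerides mmol/L, fibrinogen g/L,
sCD25 U/mL); extracts must be pre-converted.  NK-cell activity is carried
as a 0/1 abnormal-low flag in the lab value column because local
laboratory references, not a universal numeric scale, define "low".
Timestamps are timezone-naive at minute resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EhrExtract",
    "ExtractValidationError",
    "ANALYTES",
    "SERVICES",
    "load_extract",
    "write_extract",
    "empty_extract",
]

ANALYTES = (
    "ferritin",
    "hemoglobin",
    "platelets",
    "neutrophils",
    "triglycerides",
    "fibrinogen",
    "scd25",
    "nk_activity",
)
SERVICES = (
    "oncology",
    "hematology",
    "rheumatology",
    "infectious diseases",
    "immunology",
    "neurology",
)
SEXES = ("male", "female", "other")
ENCOUNTER_CLASSES = ("inpatient", "outpatient")
TEMP_ROUTES = ("oral", "other")

# Column kinds: str, opt_str, float, dt (timestamp), opt_dt, date, opt_date,
# bool, opt_bool.
SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {
        "patient_id": "str",
        "sex": "str",
        "birth_date": "date",
        "death_date": "opt_date",
    },
    "encounters": {
        "encounter_id": "str",
        "patient_id": "str",
        "encounter_class": "str",
        "start": "dt",
        "end": "opt_dt",
        "admission_diagnosis": "opt_str",
        "discharged_alive": "opt_bool",
    },
    "labs": {
        "patient_id": "str",
        "encounter_id": "str",
        "analyte": "str",
        "value": "float",
        "collected_at": "dt",
    },
    "temperatures": {
        "patient_id": "str",
        "encounter_id": "str",
        "taken_at": "dt",
        "temperature_c": "float",
        "route": "str",
    },
    "diagnoses": {
        "patient_id": "str",
        "icd10_code": "str",
        "noted_at": "dt",
        "encounter_id": "opt_str",
    },
    "treatment_plans": {
        "patient_id": "str",
        "display_name": "opt_str",
        "protocol_name": "opt_str",
        "applied_at": "dt",
        "encounter_id": "opt_str",
    },
    "medications": {
        "patient_id": "str",
        "encounter_id": "str",
        "generic_name": "str",
        "administered_at": "dt",
        "is_chemotherapy": "bool",
    },
    "notes": {
        "patient_id": "str",
        "encounter_id": "str",
        "authored_at": "dt",
        "text": "opt_str",
    },
    "pathology": {
        "patient_id": "str",
        "encounter_id": "str",
        "authored_at": "dt",
        "text": "opt_str",
        "adjudicated_positive": "opt_bool",
    },
    "icu": {
        "patient_id": "str",
        "encounter_id": "str",
        "start": "dt",
        "end": "dt",
    },
    "services": {
        "patient_id": "str",
        "encounter_id": "str",
        "service": "str",
    },
    "sct": {
        "patient_id": "str",
        "date": "date",
    },
}

# Deterministic row order for writing: stable sort on these columns.
SORT_KEYS: dict[str, list[str]] = {
    "patients": ["patient_id"],
    "encounters": ["patient_id", "start", "encounter_id"],
    "labs": ["patient_id", "encounter_id", "collected_at", "analyte", "value"],
    "temperatures": ["patient_id", "encounter_id", "taken_at", "temperature_c"],
    "diagnoses": ["patient_id", "noted_at", "icd10_code"],
    "treatment_plans": ["patient_id", "applied_at", "display_name"],
    "medications": ["patient_id", "encounter_id", "administered_at", "generic_name"],
    "notes": ["patient_id", "encounter_id", "authored_at"],
    "pathology": ["patient_id", "encounter_id", "authored_at"],
    "icu": ["patient_id", "encounter_id", "start"],
    "services": ["patient_id", "encounter_id", "service"],
    "sct": ["patient_id", "date"],
}

_ICD10_PATTERN = r"^[A-Z][0-9]+(\.[0-9]+)?$"


class ExtractValidationError(ValueError):
    """Validation failure; ``.problems`` lists row-level diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = "\n".join(problems[:25])
        extra = "" if len(problems) <= 25 else f"\n... and {len(problems) - 25} more"
        super().__init__(f"extract validation failed:\n{shown}{extra}")


@dataclass
class EhrExtract:
    """Typed bundle of EHR tables; the universal pipeline input."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    labs: pd.DataFrame
    temperatures: pd.DataFrame
    diagnoses: pd.DataFrame
    treatment_plans: pd.DataFrame
    medications: pd.DataFrame
    notes: pd.DataFrame
    pathology: pd.DataFrame
    icu: pd.DataFrame
    services: pd.DataFrame
    sct: pd.DataFrame

    def tables(self):
        """Yield ``(name, DataFrame)`` pairs in schema order."""
        for f in dc_fields(self):
            yield f.name, getattr(self, f.name)

    def copy(self) -> "EhrExtract":
        return EhrExtract(**{name: df.copy() for name, df in self.tables()})


def _empty_table(name: str) -> pd.DataFrame:
    cols = {}
    for col, kind in SCHEMAS[name].items():
        if kind in ("dt", "opt_dt", "date", "opt_date"):
            cols[col] = pd.Series([], dtype="datetime64[ns]")
        elif kind == "float":
            cols[col] = pd.Series([], dtype="float64")
        elif kind in ("bool", "opt_bool"):
            cols[col] = pd.Series([], dtype="boolean")
        else:
            cols[col] = pd.Series([], dtype="object")
    return pd.DataFrame(cols)


def empty_extract() -> EhrExtract:
    """A fully typed extract with zero rows in every table."""
    return EhrExtract(**{name: _empty_table(name) for name in SCHEMAS})


def _coerce_table(name: str, df: pd.DataFrame, problems: list[str]) -> pd.DataFrame:
    schema = SCHEMAS[name]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        problems.append(f"{name}: missing columns {missing}")
        return _empty_table(name)
    df = df[list(schema)].copy()
    for col, kind in schema.items():
        s = df[col]
        if kind in ("dt", "opt_dt", "date", "opt_date"):
            try:
                df[col] = pd.to_datetime(s, format="mixed")
            except (ValueError, TypeError) as exc:
                problems.append(f"{name}.{col}: unparseable timestamp ({exc})")
                df[col] = pd.NaT
        elif kind == "float":
            df[col] = pd.to_numeric(s, errors="coerce")
            bad = df.index[df[col].isna() & s.notna()]
            for i in bad:
                problems.append(f"{name} row {i}: non-numeric {col} {s.loc[i]!r}")
        elif kind in ("bool", "opt_bool"):
            mapped = s.map(
                {
                    True: True, False: False,
                    "true": True, "false": False,
                    "True": True, "False": False,
                    1: True, 0: False, 1.0: True, 0.0: False,
                }
            )
            bad = df.index[mapped.isna() & s.notna() & (s != "")]
            for i in bad:
                problems.append(f"{name} row {i}: non-boolean {col} {s.loc[i]!r}")
            df[col] = mapped.astype("boolean")
        else:  # str / opt_str
            df[col] = s.astype("object").where(s.notna(), None)
            if kind == "opt_str":
                df[col] = df[col].where(df[col] != "", None)
    return df


def _check_required(name, df, col, problems):
    for i in df.index[df[col].isna() | (df[col] == "")]:
        problems.append(f"{name} row {i}: missing required {col}")


def _check_enum(name, df, col, allowed, problems):
    bad = df.index[df[col].notna() & ~df[col].isin(allowed)]
    for i in bad:
        problems.append(f"{name} row {i}: {col} {df[col].loc[i]!r} not in {sorted(allowed)}")


def validate_extract(extract: EhrExtract) -> list[str]:
    """Return all invariant violations (empty list ⇒ valid)."""
    problems: list[str] = []
    pat, enc = extract.patients, extract.encounters

    for name, df in extract.tables():
        for col, kind in SCHEMAS[name].items():
            if kind in ("str", "dt", "date", "float", "bool"):
                _check_required(name, df, col, problems)

    if pat["patient_id"].duplicated().any():
        dupes = pat["patient_id"][pat["patient_id"].duplicated()].tolist()
        problems.append(f"patients: duplicate patient_id {sorted(set(dupes))}")
    _check_enum("patients", pat, "sex", SEXES, problems)
    bad = pat.index[pat["death_date"].notna() & (pat["death_date"] < pat["birth_date"])]
    for i in bad:
        problems.append(f"patients row {i}: death_date precedes birth_date")

    if enc["encounter_id"].duplicated().any():
        dupes = enc["encounter_id"][enc["encounter_id"].duplicated()].tolist()
        problems.append(f"encounters: duplicate encounter_id {sorted(set(dupes))}")
    _check_enum("encounters", enc, "encounter_class", ENCOUNTER_CLASSES, problems)
    bad = enc.index[enc["end"].notna() & (enc["end"] < enc["start"])]
    for i in bad:
        problems.append(f"encounters row {i}: end precedes start")

    _check_enum("labs", extract.labs, "analyte", ANALYTES, problems)
    bad = extract.labs.index[extract.labs["value"] < 0]
    for i in bad:
        problems.append(
            f"labs row {i}: value must be >= 0 (got {extract.labs['value'].loc[i]})"
        )

    t = extract.temperatures
    _check_enum("temperatures", t, "route", TEMP_ROUTES, problems)
    bad = t.index[(t["temperature_c"] < 30.0) | (t["temperature_c"] > 45.0)]
    for i in bad:
        problems.append(
            f"temperatures row {i}: temperature_c {t['temperature_c'].loc[i]} "
            "outside [30, 45]"
        )

    d = extract.diagnoses
    matched = d["icd10_code"].str.match(_ICD10_PATTERN).fillna(False).astype(bool)
    bad = d.index[d["icd10_code"].notna() & ~matched]
    for i in bad:
        problems.append(f"diagnoses row {i}: malformed icd10_code {d['icd10_code'].loc[i]!r}")

    tp = extract.treatment_plans
    bad = tp.index[tp["display_name"].isna() & tp["protocol_name"].isna()]
    for i in bad:
        problems.append(f"treatment_plans row {i}: display_name and protocol_name both empty")

    _check_enum("services", extract.services, "service", SERVICES, problems)

    icu = extract.icu
    bad = icu.index[icu["end"] < icu["start"]]
    for i in bad:
        problems.append(f"icu row {i}: end precedes start")

    # Referential integrity.
    known_patients = set(pat["patient_id"].dropna())
    known_encounters = set(enc["encounter_id"].dropna())
    for name, df in extract.tables():
        if name == "patients":
            continue
        if "patient_id" in df.columns:
            bad = df.index[df["patient_id"].notna() & ~df["patient_id"].isin(known_patients)]
            for i in bad:
                problems.append(f"{name} row {i}: unknown patient_id {df['patient_id'].loc[i]!r}")
        if "encounter_id" in df.columns and name != "encounters":
            present = df["encounter_id"].notna()
            bad = df.index[present & ~df["encounter_id"].isin(known_encounters)]
            for i in bad:
                problems.append(
                    f"{name} row {i}: unknown encounter_id {df['encounter_id'].loc[i]!r}"
                )
    return problems


def load_extract(directory: str | Path) -> EhrExtract:
    """Read and validate an extract directory of CSV files.

    Raises :class:`FileNotFoundError` for a missing required file and
    :class:`ExtractValidationError` with row-level diagnostics for any
    type or invariant violation.
    """
    directory = Path(directory)
    problems: list[str] = []
    tables = {}
    for name in SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"required extract file missing: {path}")
        raw = pd.read_csv(path, dtype="object", keep_default_na=False)
        raw = raw.replace({"": None})
        tables[name] = _coerce_table(name, raw, problems)
    extract = EhrExtract(**tables)
    problems.extend(validate_extract(extract))
    if problems:
        raise ExtractValidationError(problems)
    return _canonical_order(extract)


def _canonical_order(extract: EhrExtract) -> EhrExtract:
    out = {}
    for name, df in extract.tables():
        out[name] = (
            df.sort_values(SORT_KEYS[name], kind="mergesort", na_position="last")
            .reset_index(drop=True)
        )
    return EhrExtract(**out)


def _format_column(s: pd.Series, kind: str) -> pd.Series:
    if kind in ("dt", "opt_dt"):
        return s.dt.strftime("%Y-%m-%d %H:%M").where(s.notna(), "")
    if kind in ("date", "opt_date"):
        return s.dt.strftime("%Y-%m-%d").where(s.notna(), "")
    if kind in ("bool", "opt_bool"):
        return s.map({True: "true", False: "false"}).where(s.notna(), "")
    if kind == "float":
        return s.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    return s.where(s.notna(), "")


def write_extract(extract: EhrExtract, directory: str | Path) -> list[Path]:
    """Write an extract as canonical CSV files; returns the paths written.

    Output is deterministic: fixed column order, rows sorted on the
    table's key columns, ISO timestamps at minute resolution, RFC-4180
    quoting.  ``write_extract`` then ``load_extract`` round-trips
    byte-identically.
    """
    problems = validate_extract(extract)
    if problems:
        raise ExtractValidationError(problems)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    extract = _canonical_order(extract)
    written = []
    for name, df in extract.tables():
        out = pd.DataFrame(
            {col: _format_column(df[col], kind) for col, kind in SCHEMAS[name].items()}
        )
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written
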