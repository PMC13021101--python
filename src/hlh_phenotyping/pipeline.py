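"""End-to-end orchestration: extract → profiles → cohorts → reports.

``run_pipeline`` loads (and validates) an extract directory, evaluates
the criteria profiles, builds the three phenotypes and their overlap,
classifies therapy exposure, derives outcomes, runs the comparison and
the ferritin+fever screening summary, and writes all artifacts plus a
manifest with config snapshot and per-file checksums.  Outputs are
deterministic for a fixed extract, config and seed; on any failure the
partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohorts as ch
from . import outcomes as oc
from .config import StudyConfig, config_to_dict, load_config
from .criteria import evaluate_extract
from .io import load_extract

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _input_checksum(input_dir: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(input_dir.glob("*.csv")):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _report_json(report: oc.ComparisonReport) -> dict:
    def rd(x):
        return None if x is None else dataclasses.asdict(x)

    return {
        "n_treated": report.n_treated,
        "n_untreated": report.n_untreated,
        "in_hospital_mortality_risk_difference": rd(report.in_hospital_rd),
        "mortality_30d_risk_difference": rd(report.mortality30_rd),
        "length_of_stay": report.los,
        "top5_admission_diagnoses": report.top5_admission_dx,
    }


def run_pipeline(
    input_dir: str | Path,
    output_dir: str | Path,
    config: StudyConfig | str | Path | None = None,
    seed: int = 0,
) -> dict:
    """Run the full phenotyping pipeline and write artifacts.

    Returns the run manifest (also written as ``manifest.json``).
    ``seed`` only feeds the bootstrap CI of the median LOS difference.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    if not isinstance(config, StudyConfig):
        config = load_config(config)
    t0 = time.time()
    written: list[Path] = []
    output_dir.mkdir(parents=True, exist_ok=True)

    def emit(name: str, payload) -> Path:
        path = output_dir / name
        if isinstance(payload, pd.DataFrame):
            payload.to_csv(path, index=False, lineterminator="\n")
        else:
            path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        written.append(path)
        return path

    try:
        extract = load_extract(input_dir)
        profiles = evaluate_extract(extract, config)
        assignments = ch.build_phenotypes(extract, profiles, config)
        overlap = ch.compute_overlap(assignments)
        screening = ch.build_screening_cohort(profiles, config)

        members = assignments[assignments["in_criteria_cohort"]]
        idx = pd.Series(
            members["index_encounter_criteria"].values, index=members["patient_id"].values
        )
        exposures = oc.classify_therapy(extract, idx, config)
        outcome_df = oc.derive_outcomes(extract, assignments, config)
        table1 = oc.make_table1(extract, assignments, config)
        screen = oc.screening_summary(screening)

        emit("criteria_profiles.csv", profiles)
        emit("phenotypes.csv", assignments)
        emit("overlap.json", overlap)
        emit("screening_encounters.csv", screening)
        emit("table1.csv", table1.reset_index(names="row"))
        emit("table3.csv", screen.table)
        emit(
            "screening_stats.json",
            {
                "total_encounters": screen.total_encounters,
                "n_meeting_threshold": screen.n_meeting,
                "share_meeting_pct": screen.share_meeting_pct,
                "number_needed_to_screen": None
                if np.isnan(screen.number_needed_to_screen)
                else screen.number_needed_to_screen,
            },
        )
        if len(members):
            report = oc.compare_groups(
                extract, profiles, assignments, exposures, outcome_df, config, seed=seed
            )
            emit("table2.csv", report.rows)
            emit("comparison_stats.json", _report_json(report))
        emit("exposures.csv", exposures)

        manifest = {
            "config": config_to_dict(config),
            "seed": seed,
            "input_dir": str(input_dir),
            "input_checksum": _input_checksum(input_dir),
            "n_patients": len(extract.patients),
            "n_encounters": len(extract.encounters),
            "n_profiles": len(profiles),
            "cohort_sizes": {
                "icd": int(assignments["in_icd_cohort"].sum()),
                "plan": int(assignments["in_plan_cohort"].sum()),
                "criteria": int(assignments["in_criteria_cohort"].sum()),
                "union": overlap["union"],
            },
            "artifacts": {p.name: _sha256(p) for p in written},
            "elapsed_s": round(time.time() - t0, 3),
        }
        path = output_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2) + "\n")
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (output_dir / "manifest.json").unlink(missing_ok=True)
        raise
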