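"""Study configuration: thresholds, lexicons, drug lists, study window.

Every numeric cutoff used by the criteria engine and the cohort builders
lives here, so a run can be reproduced from a single YAML file.  The
defaults encode the HLH-2004 clinical criteria as operationalized over an
EHR extract: laboratory thresholds in canonical units, the two-clause oral
fever rule, the splenomegaly term lexicon with its pre-term negation
window, and the HLH-directed drug list.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

__all__ = ["CriteriaThresholds", "StudyConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


@dataclass(frozen=True)
class CriteriaThresholds:
    """Numeric cutoffs for the eight HLH-2004 clinical criteria.

    Units are canonical per analyte: ferritin µg/L, hemoglobin g/L,
    platelets and neutrophils 10⁹/L, triglycerides mmol/L, fibrinogen g/L,
    sCD25 U/mL, temperatures °C.  Inclusivity follows the criteria text:
    ferritin ≥, triglycerides ≥, sCD25 ≥, fibrinogen ≤; the three
    cytopenia lineages are strict ``<``.
    """

    ferritin_min: float = 500.0          # µg/L, inclusive
    hgb_max: float = 90.0                # g/L, exclusive (value < threshold)
    hgb_max_infant: float = 100.0        # g/L for infants under 4 weeks
    infant_age_days: int = 28            # "<4 wk", exclusive cutoff
    plt_max: float = 100.0               # 10⁹/L, exclusive
    anc_max: float = 1.0                 # 10⁹/L, exclusive
    tg_min: float = 3.0                  # mmol/L, inclusive
    fib_max: float = 1.5                 # g/L, inclusive
    scd25_min: float = 2400.0            # U/mL, inclusive
    fever_single: float = 38.3           # °C, one oral reading suffices
    fever_sustained_low: float = 38.0    # °C, sustained-run floor
    fever_sustained_high: float = 38.2   # °C, documented upper bound of clause (b)
    fever_sustained_minutes: int = 60
    criteria_required: int = 5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ConfigError(f"threshold {f.name} must be numeric, got {v!r}")
            if v <= 0:
                raise ConfigError(f"threshold {f.name} must be positive, got {v!r}")
        if not 1 <= self.criteria_required <= 8:
            raise ConfigError(
                f"criteria_required must be in [1, 8], got {self.criteria_required}"
            )


DEFAULT_SPLENOMEGALY_TERMS = (
    "splenomegaly",
    "big spleen",
    "organomegaly",
    "enlarged spleen",
)
DEFAULT_NEGATION_TERMS = ("no", "none", "absence", "without", "negative")
DEFAULT_HEMOPHAGOCYTOSIS_PATTERNS = (
    "hemophagocytosis",
    "haemophagocytosis",
    "hemophagocytic",
    "haemophagocytic",
)
DEFAULT_HLH_ICD_CODES = ("D76.1", "D76.2")
DEFAULT_PLAN_NAME_PATTERNS = ("hlh", "hemophagocytosis", "haemophagocytosis")
DEFAULT_HLH_DIRECTED_DRUGS = (
    "dexamethasone",
    "methylprednisolone",
    "anakinra",
    "ruxolitinib",
    "cyclosporine",
    "etoposide",
    "emapalumab",
)
# The two corticosteroids in the HLH-directed list; used to classify
# therapy patterns (steroid-only vs steroid-plus-other vs other-only).
DEFAULT_STEROID_DRUGS = ("dexamethasone", "methylprednisolone")


@dataclass(frozen=True)
class StudyConfig:
    """Full run configuration for the phenotyping pipeline."""

    window_start: date = date(2018, 6, 2)
    window_end: date = date(2025, 5, 31)
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)
    splenomegaly_terms: tuple[str, ...] = DEFAULT_SPLENOMEGALY_TERMS
    negation_terms: tuple[str, ...] = DEFAULT_NEGATION_TERMS
    negation_window_words: int = 3
    hemophagocytosis_patterns: tuple[str, ...] = DEFAULT_HEMOPHAGOCYTOSIS_PATTERNS
    hlh_icd_codes: tuple[str, ...] = DEFAULT_HLH_ICD_CODES
    plan_name_patterns: tuple[str, ...] = DEFAULT_PLAN_NAME_PATTERNS
    hlh_directed_drugs: tuple[str, ...] = DEFAULT_HLH_DIRECTED_DRUGS
    steroid_drugs: tuple[str, ...] = DEFAULT_STEROID_DRUGS
    mortality_window_days: int = 30
    # Stricter cytopenia reading: require ≥2 lineages low on the same
    # calendar day rather than anywhere in the episode.
    cytopenia_same_day: bool = False

    def __post_init__(self) -> None:
        if self.window_end < self.window_start:
            raise ConfigError("window_end precedes window_start")
        if self.negation_window_words < 0:
            raise ConfigError("negation_window_words must be >= 0")
        if self.mortality_window_days <= 0:
            raise ConfigError("mortality_window_days must be positive")


def _as_date(value: object, key: str) -> date:
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        return date.fromisoformat(value)
    raise ConfigError(f"{key} must be an ISO date, got {value!r}")


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML, or the defaults if absent.

    The YAML file is a flat mapping; threshold overrides go under a
    ``thresholds:`` key.  Unknown keys and non-numeric thresholds are
    rejected rather than ignored.
    """
    if path is None:
        return StudyConfig()
    path = Path(path)
    if not path.exists():
        return StudyConfig()
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")

    kwargs: dict[str, object] = {}
    thr_kwargs: dict[str, object] = {}
    thr_fields = {f.name for f in dataclasses.fields(CriteriaThresholds)}
    cfg_fields = {f.name for f in dataclasses.fields(StudyConfig)}
    for key, value in raw.items():
        if key == "thresholds":
            if not isinstance(value, dict):
                raise ConfigError("thresholds must be a mapping")
            for tk, tv in value.items():
                if tk not in thr_fields:
                    raise ConfigError(f"unknown threshold {tk!r}")
                thr_kwargs[tk] = tv
        elif key in thr_fields:
            # Allow flat threshold overrides for convenience.
            thr_kwargs[key] = value
        elif key in cfg_fields:
            if key in ("window_start", "window_end"):
                value = _as_date(value, key)
            elif isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key {key!r}")
    kwargs["thresholds"] = CriteriaThresholds(**thr_kwargs)
    return StudyConfig(**kwargs)


def config_to_dict(config: StudyConfig) -> dict:
    """Serializable snapshot of a config (for the run manifest / echo)."""
    d = dataclasses.asdict(config)
    d["window_start"] = config.window_start.isoformat()
    d["window_end"] = config.window_end.isoformat()
    for key, value in list(d.items()):
        if isinstance(value, tuple):
            d[key] = list(value)
    return d
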