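"""Study configuration: windows, thresholds, and editable code sets.

The study design follows a fixed three-year observation window (a study
period containing a one-year selection period) with a maximum two-year
lookback from each patient's index date. All intervals in the package are
half-open ``[start, end)`` and all dates are ISO-8601 calendar dates.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from importlib import resources
from typing import Mapping

import yaml

DATE_MIN = dt.date(1900, 1, 1)
DATE_MAX = dt.date(2100, 1, 1)


def _load_package_yaml(name: str) -> dict:
    with resources.files("si_pheno.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


def default_code_sets() -> dict[str, list[str]]:
    """ICD-10 prefix sets defining cohort subgroups and SAMS."""
    cfg = _load_package_yaml("code_sets.yaml")["cohort"]
    cfg["sams"] = _load_package_yaml("sams_codes.yaml")["sams"]
    return {k: list(v) for k, v in cfg.items()}


def default_atc_sets() -> dict[str, list[str]]:
    """ATC prefix sets for lipid-lowering therapy classes."""
    return {k: list(v) for k, v in _load_package_yaml("code_sets.yaml")["atc"].items()}


def default_intensity_spec() -> dict[str, dict]:
    return dict(_load_package_yaml("intensity_map.yaml")["statins"])


@dataclasses.dataclass
class StudyConfig:
    """Windows, adherence thresholds, and code/ATC vocabularies for one study.

    Defaults reproduce the design of a German outpatient EMR study:
    study period March 2017 - March 2020, selection period March 2019 -
    March 2020, two-year lookback, and a >180-day gap defining long-term
    statin discontinuation.
    """

    study_start: dt.date = dt.date(2017, 3, 1)
    study_end: dt.date = dt.date(2020, 3, 31)
    selection_start: dt.date = dt.date(2019, 3, 1)
    selection_end: dt.date = dt.date(2020, 3, 31)
    lookback_days: int = 730
    gap_days: int = 180
    default_days_supplied: int = 30
    mpr_threshold: float = 0.5
    min_scripts_for_mpr: int = 3
    # feature engineering / selection
    discrete_cardinality_threshold: int = 20
    mi_neighbors: int = 3
    n_selected_features: int = 400
    # calibration
    n_tolerant_sample: int = 50_000
    code_sets: dict[str, list[str]] = dataclasses.field(default_factory=default_code_sets)
    atc_sets: dict[str, list[str]] = dataclasses.field(default_factory=default_atc_sets)
    intensity_spec: dict[str, dict] = dataclasses.field(default_factory=default_intensity_spec)

    def __post_init__(self) -> None:
        if not (self.study_start < self.selection_start < self.selection_end <= self.study_end):
            raise ValueError("require study_start < selection_start < selection_end <= study_end")
        if self.gap_days <= 0 or self.lookback_days <= 0:
            raise ValueError("gap_days and lookback_days must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        """Build a config from a YAML file; unspecified keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "StudyConfig":
        kwargs: dict = {}
        date_fields = {"study_start", "study_end", "selection_start", "selection_end"}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise KeyError(f"unknown study config key: {key!r}")
            if key in date_fields and isinstance(value, str):
                value = dt.date.fromisoformat(value)
            kwargs[key] = value
        return cls(**kwargs)

    def code_prefixes(self, phenotype: str) -> list[str]:
        try:
            return self.code_sets[phenotype]
        except KeyError:
            raise KeyError(f"unknown phenotype code set: {phenotype!r}") from None


def matches_any_prefix(code: str, prefixes: list[str]) -> bool:
    """ICD-10/ATC prefix match; '.' suffixes match their subcodes too."""
    return any(code.startswith(p) for p in prefixes)
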