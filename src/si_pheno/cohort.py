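"""Cohort eligibility, index dates, lookback windows and diagnosis subgroups.

Eligibility (applied in order, each step counted in the attrition report):

1. age >= 18 years at the index date,
2. at least one consultation (any dated event) during the selection period,
3. at least one lipid-lowering prescription (ATC C10*) during the study period,
4. at least one qualifying diagnosis (ASCVD, high CV risk, or
   hypercholesterolemia) at any time.

The index date is the latest statin prescription inside the study period;
patients on non-statin LLT only are anchored at their latest non-statin LLT
prescription. The lookback window is ``[max(study_start, index - lookback),
index]``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import pandas as pd

from .config import StudyConfig, matches_any_prefix
from .data_model import PatientRecord

SUBGROUPS = ("ascvd", "high_cv_risk", "hypercholesterolemia")

ATTRITION_STEPS = ("age", "consultation", "llt", "diagnosis")


@dataclasses.dataclass
class CohortEntry:
    patient_id: str
    index_date: dt.date
    lookback_start: dt.date
    subgroups: set[str]
    age_at_index: int
    has_statin_history: bool


@dataclasses.dataclass
class AttritionReport:
    n_input: int
    removed: dict[str, int]
    n_eligible: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "input", "n": self.n_input}]
        remaining = self.n_input
        for step in ATTRITION_STEPS:
            remaining -= self.removed[step]
            rows.append({"step": f"removed_{step}", "n": self.removed[step]})
        rows.append({"step": "eligible", "n": self.n_eligible})
        return pd.DataFrame(rows)


def is_statin_atc(atc: str, config: StudyConfig) -> bool:
    return matches_any_prefix(atc, config.atc_sets["statin"])


def is_llt_atc(atc: str, config: StudyConfig) -> bool:
    return matches_any_prefix(atc, config.atc_sets["llt"])


def find_index_date(record: PatientRecord, config: StudyConfig) -> tuple[dt.date | None, bool]:
    """Return (index_date, has_statin_history) for one patient.

    Statin users are anchored at their latest statin script in the study
    period; non-statin LLT users at their latest non-statin LLT script.
    """
    statin_dates, llt_dates = [], []
    for rx in record.prescriptions:
        if not (config.study_start <= rx.date < config.study_end):
            continue
        if is_statin_atc(rx.atc, config):
            statin_dates.append(rx.date)
        elif is_llt_atc(rx.atc, config):
            llt_dates.append(rx.date)
    if statin_dates:
        return max(statin_dates), True
    if llt_dates:
        return max(llt_dates), False
    return None, False


def tag_subgroups(record: PatientRecord, config: StudyConfig) -> set[str]:
    """Diagnosis-subgroup tags from configured ICD-10 prefix sets (any date)."""
    tags = set()
    for name in SUBGROUPS:
        prefixes = config.code_prefixes(name)
        if any(matches_any_prefix(d.icd10, prefixes) for d in record.diagnoses):
            tags.add(name)
    return tags


def _had_consultation(record: PatientRecord, config: StudyConfig) -> bool:
    # Visits are recorded by date; any dated event marks a consultation.
    dates = [d.date for d in record.diagnoses] + [p.date for p in record.prescriptions]
    return any(config.selection_start <= d < config.selection_end for d in dates)


def _had_llt(record: PatientRecord, config: StudyConfig) -> bool:
    return any(
        is_llt_atc(p.atc, config) and config.study_start <= p.date < config.study_end
        for p in record.prescriptions
    )


def select_cohort(
    records: list[PatientRecord], config: StudyConfig
) -> tuple[list[CohortEntry], AttritionReport]:
    """Apply the four eligibility criteria in order; return entries + attrition."""
    removed = {step: 0 for step in ATTRITION_STEPS}
    entries: list[CohortEntry] = []
    for record in records:
        index_date, has_statin = find_index_date(record, config)
        # Age is assessed at the index date; for patients without any LLT
        # anchor (who fail the LLT step anyway) the selection end stands in.
        age_anchor = index_date if index_date is not None else config.selection_end
        age = age_anchor.year - record.birth_year
        if age < 18:
            removed["age"] += 1
            continue
        if not _had_consultation(record, config):
            removed["consultation"] += 1
            continue
        if index_date is None or not _had_llt(record, config):
            removed["llt"] += 1
            continue
        subgroups = tag_subgroups(record, config)
        if not subgroups:
            removed["diagnosis"] += 1
            continue
        lookback_start = max(
            config.study_start, index_date - dt.timedelta(days=config.lookback_days)
        )
        entries.append(
            CohortEntry(
                patient_id=record.patient_id,
                index_date=index_date,
                lookback_start=lookback_start,
                subgroups=subgroups,
                age_at_index=age,
                has_statin_history=has_statin,
            )
        )
    report = AttritionReport(
        n_input=len(records), removed=removed, n_eligible=len(entries)
    )
    return entries, report
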