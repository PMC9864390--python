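"""Study-shaped outputs: prevalence and characteristics tables, first-event
down-titration/switch matrices, the attrition flow, and the end-to-end
pipeline driver.

All printed percentages are column percentages rounded half-up to one
decimal. Reports are pure functions of upstream artifacts.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import CalibrationResult, calibrate, round_percent
from .cohort import AttritionReport, CohortEntry, select_cohort
from .config import StudyConfig, matches_any_prefix
from .data_model import PatientRecord, read_emr_dir
from .features import build_features, select_features
from .si_rules import LABELS, SIClassification, classifications_to_frame, classify_cohort
from .statin_events import SIEventProfile, build_profile

logger = logging.getLogger(__name__)

AGE_BANDS = ((18, 30), (30, 50), (50, 70), (70, None))

_CHARACTERISTIC_CODES = {
    "sams_myalgia": ["M79.1"],
    "sams_myositis": ["M60.8", "M60.9"],
    "sams_myopathy": ["G72.0", "G72.9"],
    "sams_cramps_spasms": ["R25.2"],
    "risk_obesity": ["E66"],
    "risk_hypothyroidism": ["E03"],
    "risk_vitamin_d_deficiency": ["E55"],
    "risk_chronic_kidney_disease": ["N18.3", "N18.4", "N18.5"],
}


def _band_name(lo: int, hi: int | None) -> str:
    return f"age_{lo}_{hi}" if hi else f"age_{lo}_plus"


def characteristics_table(
    records: list[PatientRecord],
    entries: list[CohortEntry],
    classifications: list[SIClassification],
    config: StudyConfig,
) -> pd.DataFrame:
    """Counts and column percentages of characteristics per label column."""
    by_pid = {r.patient_id: r for r in records}
    entry_by_pid = {e.patient_id: e for e in entries}
    columns = list(LABELS) + ["total"]
    col_members: dict[str, list[str]] = {c: [] for c in columns}
    for c in classifications:
        col_members[c.label].append(c.patient_id)
        col_members["total"].append(c.patient_id)

    statin_molecules = sorted(config.intensity_spec)

    def row_members(pids: list[str]):
        rows: dict[str, int] = {}

        def bump(name: str):
            rows[name] = rows.get(name, 0) + 1

        for pid in pids:
            record, entry = by_pid[pid], entry_by_pid[pid]
            for lo, hi in AGE_BANDS:
                if entry.age_at_index >= lo and (hi is None or entry.age_at_index < hi):
                    bump(_band_name(lo, hi))
                    break
            bump(f"gender_{record.gender}")
            for sg in sorted(entry.subgroups):
                bump(f"subgroup_{sg}")
            window_end = entry.index_date + dt.timedelta(days=1)
            codes = {
                d.icd10
                for d in record.diagnoses
                if entry.lookback_start <= d.date < window_end
            }
            for name, prefixes in _CHARACTERISTIC_CODES.items():
                if any(matches_any_prefix(code, prefixes) for code in codes):
                    bump(name)
            molecules = {
                p.molecule
                for p in record.prescriptions
                if entry.lookback_start <= p.date < window_end
            }
            for mol in statin_molecules:
                if mol in molecules:
                    bump(f"statin_{mol}")
            if "ezetimibe" in molecules:
                bump("nonstatin_ezetimibe")
            if molecules & {"fenofibrate", "bezafibrate"}:
                bump("nonstatin_fibrate")
        return rows

    all_rows: dict[str, dict[str, int]] = {c: row_members(col_members[c]) for c in columns}
    row_names = [_band_name(lo, hi) for lo, hi in AGE_BANDS]
    row_names += [f"gender_{g}" for g in ("female", "male", "unspecified")]
    row_names += [f"subgroup_{s}" for s in ("ascvd", "high_cv_risk", "hypercholesterolemia")]
    row_names += list(_CHARACTERISTIC_CODES)
    row_names += [f"statin_{m}" for m in statin_molecules]
    row_names += ["nonstatin_ezetimibe", "nonstatin_fibrate"]

    out = []
    for name in row_names:
        row = {"characteristic": name}
        for col in columns:
            n_col = len(col_members[col])
            count = all_rows[col].get(name, 0)
            row[f"{col}_n"] = count
            row[f"{col}_pct"] = round_percent(count, n_col) if n_col else 0.0
        out.append(row)
    header = {"characteristic": "n"}
    for col in columns:
        header[f"{col}_n"] = len(col_members[col])
        header[f"{col}_pct"] = 100.0
    return pd.DataFrame([header] + out)


def transition_matrices(
    profiles: dict[str, SIEventProfile],
    classifications: list[SIClassification],
) -> dict[str, pd.DataFrame]:
    """First down-titration and first switch matrices per high-confidence class.

    Rows are the originating (molecule, dose) pair, columns the destination;
    each patient contributes at most one cell per matrix.
    """
    groups = {
        "absolute": [c.patient_id for c in classifications if c.label == "absolute_high"],
        "partial": [c.patient_id for c in classifications if c.label == "partial_high"],
    }
    out: dict[str, pd.DataFrame] = {}
    for group, pids in groups.items():
        for kind, attr in (
            ("down_titration", "first_down_titration"),
            ("switch", "first_switch"),
        ):
            cells: dict[tuple[str, str], int] = {}
            for pid in pids:
                event = getattr(profiles[pid], attr)
                if event is None:
                    continue
                a, b = event
                key = (f"{a.molecule} {a.dose_mg:g}mg", f"{b.molecule} {b.dose_mg:g}mg")
                cells[key] = cells.get(key, 0) + 1
            if cells:
                frame = (
                    pd.Series(cells).rename_axis(["from", "to"]).unstack(fill_value=0)
                )
            else:
                frame = pd.DataFrame()
            out[f"{group}_{kind}"] = frame
    return out


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    data_dir,
    out_dir,
    config: StudyConfig | None = None,
    seed: int = 0,
    n_features: int | None = None,
) -> dict:
    """cohort -> events -> rules -> features -> calibration -> reports.

    Reads the three interchange CSVs from ``data_dir`` and writes
    prevalence.csv, characteristics.csv, classifications.csv, the two
    first-event matrices, attrition.csv, model_report.json and a run
    manifest to ``out_dir``. Deterministic for a fixed seed.
    """
    config = config or StudyConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    stage("load")
    records, load_report = read_emr_dir(data_dir, config)

    stage("cohort")
    entries, attrition = select_cohort(records, config)
    attrition.to_frame().to_csv(out_dir / "attrition.csv", index=False)

    stage("events")
    by_pid = {r.patient_id: r for r in records}
    profiles = {
        e.patient_id: build_profile(by_pid[e.patient_id], e, config) for e in entries
    }

    stage("rules")
    classifications, rule_table = classify_cohort(entries, profiles, config)
    classifications_to_frame(classifications).to_csv(
        out_dir / "classifications.csv", index=False
    )

    stage("features")
    matrix = build_features(records, entries, config)
    labels_binary = (
        classifications_to_frame(classifications)
        .set_index("patient_id")["label"]
        .loc[matrix.patient_ids]
        != "tolerant"
    ).to_numpy(dtype=int)
    k = n_features or config.n_selected_features
    selection = select_features(
        matrix,
        labels_binary,
        k=k,
        k_neighbors=config.mi_neighbors,
        discrete_cardinality_threshold=config.discrete_cardinality_threshold,
    )

    stage("calibration")
    result = calibrate(
        matrix,
        classifications,
        seed=seed,
        n_tolerant=config.n_tolerant_sample,
        feature_subset=selection.selected,
    )

    stage("reports")
    prevalence = pd.concat(
        [result.prevalence_before.to_frame(), result.prevalence_after.to_frame()]
    )
    prevalence.to_csv(out_dir / "prevalence.csv", index=False)
    characteristics_table(records, entries, classifications, config).to_csv(
        out_dir / "characteristics.csv", index=False
    )
    matrices = transition_matrices(profiles, classifications)
    for name, frame in matrices.items():
        frame.to_csv(out_dir / f"{name}_matrix.csv")
    model_report = {
        si_class: [
            {
                "family": r.family,
                "selected": r.selected,
                "fold_f1": r.fold_f1,
                "fold_roc_auc": r.fold_roc_auc,
                "fold_pr_auc": r.fold_pr_auc,
                "mean_f1": r.mean_f1,
                "mean_roc_auc": r.mean_roc_auc,
                "mean_pr_auc": r.mean_pr_auc,
            }
            for r in reports
        ]
        for si_class, reports in result.model_reports.items()
    }
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_records": len(records),
        "n_eligible": len(entries),
        "load_report": vars(load_report),
        "thresholds": result.threshold,
        "selected_features": len(selection.selected),
    }
    (out_dir / "model_report.json").write_text(json.dumps(model_report, indent=2))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "entries": entries,
        "profiles": profiles,
        "classifications": classifications,
        "rule_table": rule_table,
        "selection": selection,
        "calibration": result,
        "manifest": manifest,
    }
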