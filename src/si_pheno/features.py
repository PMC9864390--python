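"""Patient-level feature matrix and mutual-information feature selection.

Features are built from each patient's lookback window:

* presence and count per 3-character ICD-10 group,
* presence and count per ATC level-4 class,
* demographics (age at index, one-hot gender),
* utilization: total prescriptions, distinct molecules, distinct ATC
  classes, distinct lipid-lowering molecules, and distinct active days
  (a proxy for physician visits).

Selection scores every feature by its mutual information with the binary
intolerant-vs-tolerant target and keeps the top ``k`` (default 400, capped
at the number of available columns). Low-cardinality features are scored
with the plug-in (histogram) estimator; continuous features with the
k-nearest-neighbour entropy estimator.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif
from sklearn.metrics import mutual_info_score

from .config import StudyConfig, matches_any_prefix
from .cohort import CohortEntry
from .data_model import PatientRecord

FEATURE_KINDS = ("presence", "frequency", "demographic", "utilization")


@dataclasses.dataclass
class FeatureMatrix:
    values: pd.DataFrame  # patients x features, indexed by patient_id
    feature_kinds: dict[str, str]

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclasses.dataclass
class SelectionResult:
    scores: dict[str, float]
    selected: list[str]
    k: int


def build_features(
    records: list[PatientRecord],
    entries: list[CohortEntry],
    config: StudyConfig,
) -> FeatureMatrix:
    """Assemble the lookback feature matrix for all cohort entries."""
    by_pid = {r.patient_id: r for r in records}
    llt_prefixes = config.atc_sets["llt"]

    dx_rows: list[tuple[str, str]] = []
    rx_rows: list[tuple[str, str]] = []
    base_rows: list[dict] = []
    for entry in entries:
        record = by_pid[entry.patient_id]
        end = entry.index_date + dt.timedelta(days=1)
        dates: set[dt.date] = set()
        n_rx = 0
        molecules: set[str] = set()
        atc4: set[str] = set()
        llt_molecules: set[str] = set()
        for d in record.diagnoses:
            if entry.lookback_start <= d.date < end:
                dx_rows.append((entry.patient_id, d.icd10[:3]))
                dates.add(d.date)
        for p in record.prescriptions:
            if entry.lookback_start <= p.date < end:
                rx_rows.append((entry.patient_id, p.atc[:5]))
                dates.add(p.date)
                n_rx += 1
                molecules.add(p.molecule)
                atc4.add(p.atc[:5])
                if matches_any_prefix(p.atc, llt_prefixes):
                    llt_molecules.add(p.molecule)
        base_rows.append(
            {
                "patient_id": entry.patient_id,
                "age": float(entry.age_at_index),
                "gender_female": float(record.gender == "female"),
                "gender_male": float(record.gender == "male"),
                "gender_unspecified": float(record.gender == "unspecified"),
                "n_prescriptions": float(n_rx),
                "n_distinct_molecules": float(len(molecules)),
                "n_distinct_atc_classes": float(len(atc4)),
                "n_distinct_llt_molecules": float(len(llt_molecules)),
                "n_visit_days": float(len(dates)),
            }
        )

    base = pd.DataFrame(base_rows).set_index("patient_id")
    pieces = [base]
    kinds = {"age": "demographic"}
    for col in ("gender_female", "gender_male", "gender_unspecified"):
        kinds[col] = "demographic"
    for col in (
        "n_prescriptions",
        "n_distinct_molecules",
        "n_distinct_atc_classes",
        "n_distinct_llt_molecules",
        "n_visit_days",
    ):
        kinds[col] = "utilization"

    for prefix, rows in (("dx", dx_rows), ("rx", rx_rows)):
        if rows:
            long = pd.DataFrame(rows, columns=["patient_id", "code"])
            counts = (
                long.groupby(["patient_id", "code"]).size().unstack(fill_value=0)
            )
            counts = counts.reindex(base.index, fill_value=0)
            counts = counts[sorted(counts.columns)]
            count_cols = counts.add_prefix(f"{prefix}_").add_suffix("_count")
            pres_cols = (counts > 0).astype(float).add_prefix(f"{prefix}_").add_suffix(
                "_present"
            )
            for c in count_cols.columns:
                kinds[c] = "frequency"
            for c in pres_cols.columns:
                kinds[c] = "presence"
            pieces.append(count_cols.astype(float))
            pieces.append(pres_cols)

    matrix = pd.concat(pieces, axis=1)
    return FeatureMatrix(values=matrix, feature_kinds=kinds)


def mutual_information(
    feature: np.ndarray,
    target: np.ndarray,
    k_neighbors: int = 3,
    discrete_cardinality_threshold: int = 20,
    random_state: int = 0,
) -> float:
    """MI (nats) between one feature vector and a binary target.

    Dispatches on cardinality: low-cardinality features use the plug-in
    (contingency-table) estimator; continuous features use the k-NN
    entropy estimator for a continuous variable against a discrete target.
    Results are clipped at zero.
    """
    feature = np.asarray(feature, dtype=float)
    target = np.asarray(target)
    if feature.shape[0] != target.shape[0] or feature.shape[0] < 10:
        raise ValueError("feature and target must share length >= 10")
    if len(np.unique(target)) < 2:
        raise ValueError("mutual information undefined for a constant target")
    if len(np.unique(feature)) <= discrete_cardinality_threshold:
        mi = mutual_info_score(target, feature)
    else:
        mi = float(
            mutual_info_classif(
                feature.reshape(-1, 1),
                target,
                discrete_features=False,
                n_neighbors=k_neighbors,
                random_state=random_state,
            )[0]
        )
    return max(float(mi), 0.0)


def select_features(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    k: int = 400,
    k_neighbors: int = 3,
    discrete_cardinality_threshold: int = 20,
) -> SelectionResult:
    """Score every column and keep the top-k; ties break by column order."""
    if k <= 0:
        raise ValueError("k must be positive")
    labels = np.asarray(labels)
    scores: dict[str, float] = {}
    for name in matrix.feature_names:
        col = matrix.values[name].to_numpy()
        if len(np.unique(col)) == 1:
            scores[name] = 0.0
            continue
        scores[name] = mutual_information(
            col,
            labels,
            k_neighbors=k_neighbors,
            discrete_cardinality_threshold=discrete_cardinality_threshold,
        )
    order = sorted(
        range(len(matrix.feature_names)),
        key=lambda i: (-scores[matrix.feature_names[i]], i),
    )
    k_eff = min(k, len(matrix.feature_names))
    selected = [matrix.feature_names[i] for i in order[:k_eff]]
    return SelectionResult(scores=scores, selected=selected, k=k_eff)
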