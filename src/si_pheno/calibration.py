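"""Supervised calibration of the rule-based prevalence estimate.

Two independent binary tasks share one feature matrix: high-confidence
absolute intolerant vs tolerant, and high-confidence partial intolerant vs
tolerant. For each task three model families (logistic regression and two
gradient-boosted-tree libraries) are evaluated on identical stratified
4-fold splits; the family with the highest mean F1 is refit on the full
training set. The decision threshold is tuned on pooled out-of-fold scores
to the point where precision equals recall (equivalently, false positives
equal false negatives), and the fitted model then reclassifies the
corresponding low-confidence patients as intolerant or tolerant. The
prevalence table is updated by moving predicted-intolerant patients from
the low- to the high-confidence row; the total intolerant count is
conserved by construction.
"""

from __future__ import annotations

import dataclasses
import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .features import FeatureMatrix
from .si_rules import SIClassification

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("logistic", "lightgbm", "xgboost")
HIGH_LABEL = {"absolute": "absolute_high", "partial": "partial_high"}
LOW_LABEL = {"absolute": "absolute_low", "partial": "partial_low"}


def round_percent(count: int, total: int) -> float:
    """Column percentage, half-up to one decimal (table formatting rule)."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class TrainingSet:
    X: pd.DataFrame
    y: np.ndarray
    positive_ids: list[str]
    negative_ids: list[str]


@dataclasses.dataclass
class ModelReport:
    family: str
    fold_f1: list[float]
    fold_roc_auc: list[float]
    fold_pr_auc: list[float]
    selected: bool = False

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self.fold_roc_auc))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self.fold_pr_auc))


@dataclasses.dataclass
class PrevalenceTable:
    stage: str  # rules_only | rules_plus_ml
    total: int
    counts: dict[str, int]  # tolerant + the four SI labels

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("prevalence counts must sum to the total")

    def percentage(self, label: str) -> float:
        return round_percent(self.counts[label], self.total)

    @property
    def si_total(self) -> int:
        return self.total - self.counts["tolerant"]

    @property
    def high_confidence_total(self) -> int:
        return self.counts["absolute_high"] + self.counts["partial_high"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, n in self.counts.items():
            rows.append(
                {"stage": self.stage, "label": label, "count": n,
                 "percent": self.percentage(label)}
            )
        rows.append(
            {"stage": self.stage, "label": "si_total", "count": self.si_total,
             "percent": round_percent(self.si_total, self.total)}
        )
        rows.append(
            {"stage": self.stage, "label": "high_confidence_total",
             "count": self.high_confidence_total,
             "percent": round_percent(self.high_confidence_total, self.total)}
        )
        return pd.DataFrame(rows)


@dataclasses.dataclass
class CalibrationResult:
    threshold: dict[str, float]
    precision_at_threshold: dict[str, float]
    recall_at_threshold: dict[str, float]
    model_reports: dict[str, list[ModelReport]]
    reclassified: dict[str, str]  # patient_id -> intolerant | tolerant
    prevalence_before: PrevalenceTable
    prevalence_after: PrevalenceTable


def make_training_set(
    matrix: FeatureMatrix,
    classifications: list[SIClassification],
    si_class: str,
    n_tolerant: int = 50_000,
    seed: int = 0,
) -> TrainingSet:
    """All high-confidence positives of one class + a seeded tolerant sample."""
    if si_class not in HIGH_LABEL:
        raise ValueError("si_class must be 'absolute' or 'partial'")
    label_by_pid = {c.patient_id: c.label for c in classifications}
    pos = [pid for pid in matrix.patient_ids if label_by_pid.get(pid) == HIGH_LABEL[si_class]]
    tol = [pid for pid in matrix.patient_ids if label_by_pid.get(pid) == "tolerant"]
    if not pos:
        raise ValueError(f"no high-confidence {si_class} patients to train on")
    rng = np.random.default_rng(seed)
    if n_tolerant < len(tol):
        neg = [tol[i] for i in sorted(rng.choice(len(tol), size=n_tolerant, replace=False))]
    else:
        if n_tolerant > len(tol):
            logger.warning(
                "requested %d tolerant negatives but only %d available; using all",
                n_tolerant, len(tol),
            )
        neg = tol
    ids = pos + neg
    X = matrix.values.loc[ids]
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    return TrainingSet(X=X, y=y, positive_ids=pos, negative_ids=neg)


def _make_model(family: str, seed: int):
    if family == "logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=1000, random_state=seed)),
            ]
        )
    if family == "lightgbm":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbosity=-1)
    if family == "xgboost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, tree_method="hist", eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown model family: {family!r}")


def crossval_train(
    ts: TrainingSet, seed: int = 0, n_folds: int = 4
) -> tuple[object, list[ModelReport], np.ndarray]:
    """Evaluate all families on identical folds; refit the F1 winner.

    Returns (fitted winner, per-family reports, pooled out-of-fold scores of
    the winning family aligned with ts rows).
    """
    X = ts.X.astype(float)
    y = ts.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for _, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("degenerate fold: a split lost one of the classes")

    reports: list[ModelReport] = []
    oof_by_family: dict[str, np.ndarray] = {}
    for family in MODEL_FAMILIES:
        f1s, rocs, prs = [], [], []
        oof = np.zeros(len(y))
        for train_idx, test_idx in folds:
            model = _make_model(family, seed)
            model.fit(X.iloc[train_idx], y[train_idx])
            scores = model.predict_proba(X.iloc[test_idx])[:, 1]
            oof[test_idx] = scores
            f1s.append(f1_score(y[test_idx], (scores >= 0.5).astype(int)))
            rocs.append(roc_auc_score(y[test_idx], scores))
            prs.append(average_precision_score(y[test_idx], scores))
        reports.append(ModelReport(family, f1s, rocs, prs))
        oof_by_family[family] = oof

    winner = max(reports, key=lambda r: r.mean_f1)
    winner.selected = True
    final = _make_model(winner.family, seed)
    final.fit(X, y)
    return final, reports, oof_by_family[winner.family]


def find_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """Threshold (from the midpoint sweep) minimizing |precision - recall|.

    Ties resolve to the lowest threshold. At an exact crossing the false
    positive and false negative counts are equal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to tune a threshold")
    uniq = np.unique(scores)
    candidates = [0.0] + [float((a + b) / 2) for a, b in zip(uniq, uniq[1:])]
    n_pos = labels.sum()
    best = None
    for t in candidates:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        pp = int(pred.sum())
        if pp == 0:
            continue
        precision = tp / pp
        recall = tp / n_pos
        gap = abs(precision - recall)
        if best is None or gap < best[0] - 1e-12:
            best = (gap, t, precision, recall)
    _, threshold, precision, recall = best
    return threshold, precision, recall


def reclassify_low_confidence(
    model, threshold: float, matrix: FeatureMatrix, low_ids: list[str]
) -> dict[str, str]:
    """Predict intolerant/tolerant for every low-confidence patient."""
    if not low_ids:
        return {}
    X = matrix.values.loc[low_ids].astype(float)
    scores = model.predict_proba(X)[:, 1]
    return {
        pid: ("intolerant" if s >= threshold else "tolerant")
        for pid, s in zip(low_ids, scores)
    }


def update_prevalence(
    rule_counts: dict[str, int],
    n_reclassified: dict[str, int],
    total: int | None = None,
) -> tuple[PrevalenceTable, PrevalenceTable]:
    """Move predicted-intolerant patients from low- to high-confidence rows.

    ``rule_counts`` holds the five stage-1 label counts; ``n_reclassified``
    maps 'absolute'/'partial' to the number of low-confidence patients the
    models predicted intolerant. Tolerant, total, and combined SI counts are
    unchanged by construction.
    """
    counts = dict(rule_counts)
    total = total if total is not None else sum(counts.values())
    if "tolerant" not in counts:
        counts["tolerant"] = total - sum(counts.values())
    before = PrevalenceTable(stage="rules_only", total=total, counts=counts)
    after_counts = dict(counts)
    for si_class, moved in n_reclassified.items():
        hi, lo = HIGH_LABEL[si_class], LOW_LABEL[si_class]
        if moved > counts[lo]:
            raise ValueError(
                f"cannot move {moved} patients out of {counts[lo]} {lo} patients"
            )
        after_counts[hi] = counts[hi] + moved
        after_counts[lo] = counts[lo] - moved
    after = PrevalenceTable(stage="rules_plus_ml", total=total, counts=after_counts)
    return before, after


def feature_importance(model, X: pd.DataFrame, y=None, seed: int = 0) -> pd.Series:
    """Mean-|attribution| per feature, descending.

    Tree families use their native Shapley-value attributions; the linear
    pipeline falls back to permutation importance.
    """
    names = list(X.columns)
    values = X.astype(float)
    if isinstance(model, LGBMClassifier):
        contrib = model.predict(values, pred_contrib=True)[:, :-1]
        imp = np.abs(contrib).mean(axis=0)
    elif isinstance(model, XGBClassifier):
        import xgboost as xgb

        dmat = xgb.DMatrix(values.to_numpy(), feature_names=names)
        contrib = model.get_booster().predict(dmat, pred_contribs=True)[:, :-1]
        imp = np.abs(contrib).mean(axis=0)
    else:
        if y is None:
            raise ValueError("permutation importance needs labels")
        res = permutation_importance(
            model, values, np.asarray(y), n_repeats=5, random_state=seed, scoring="roc_auc"
        )
        imp = np.abs(res.importances_mean)
    return pd.Series(imp, index=names).sort_values(ascending=False)


def calibrate(
    matrix: FeatureMatrix,
    classifications: list[SIClassification],
    seed: int = 0,
    n_tolerant: int = 50_000,
    feature_subset: list[str] | None = None,
) -> CalibrationResult:
    """Run both model tasks end to end and update the prevalence table."""
    if feature_subset is not None:
        matrix = FeatureMatrix(
            values=matrix.values[feature_subset],
            feature_kinds={k: matrix.feature_kinds[k] for k in feature_subset},
        )
    label_by_pid = {c.patient_id: c.label for c in classifications}
    rule_counts = {
        lbl: sum(1 for c in classifications if c.label == lbl)
        for lbl in ("tolerant", "absolute_high", "absolute_low", "partial_high", "partial_low")
    }
    thresholds, precisions, recalls = {}, {}, {}
    reports: dict[str, list[ModelReport]] = {}
    reclassified: dict[str, str] = {}
    n_moved: dict[str, int] = {}
    for si_class in ("absolute", "partial"):
        ts = make_training_set(
            matrix, classifications, si_class, n_tolerant=n_tolerant, seed=seed
        )
        model, fam_reports, oof = crossval_train(ts, seed=seed)
        thr, prec, rec = find_threshold(oof, ts.y)
        low_ids = [
            pid for pid in matrix.patient_ids
            if label_by_pid.get(pid) == LOW_LABEL[si_class]
        ]
        predictions = reclassify_low_confidence(model, thr, matrix, low_ids)
        reclassified.update(predictions)
        n_moved[si_class] = sum(1 for v in predictions.values() if v == "intolerant")
        thresholds[si_class] = thr
        precisions[si_class] = prec
        recalls[si_class] = rec
        reports[si_class] = fam_reports
    before, after = update_prevalence(rule_counts, n_moved)
    return CalibrationResult(
        threshold=thresholds,
        precision_at_threshold=precisions,
        recall_at_threshold=recalls,
        model_reports=reports,
        reclassified=reclassified,
        prevalence_before=before,
        prevalence_after=after,
    )
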