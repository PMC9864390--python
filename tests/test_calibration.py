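import dataclasses

import numpy as np
import pandas as pd
import pytest

from si_pheno.calibration import (
    crossval_train,
    feature_importance,
    find_threshold,
    make_training_set,
    round_percent,
    update_prevalence,
    TrainingSet,
)
from si_pheno.features import FeatureMatrix
from si_pheno.si_rules import SIClassification


def _matrix(values: np.ndarray, ids=None) -> FeatureMatrix:
    ids = ids or [f"P{i}" for i in range(len(values))]
    cols = [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(
        values=pd.DataFrame(values, index=ids, columns=cols),
        feature_kinds={c: "frequency" for c in cols},
    )


def _classifications(labels):
    return [
        SIClassification(f"P{i}", lbl, None if lbl == "tolerant" else "r", frozenset())
        for i, lbl in enumerate(labels)
    ]


def test_training_set_counts_and_determinism():
    labels = ["absolute_high"] * 100 + ["tolerant"] * 10_000
    matrix = _matrix(np.random.default_rng(0).random((10_100, 3)))
    cls = _classifications(labels)
    ts1 = make_training_set(matrix, cls, "absolute", n_tolerant=500, seed=4)
    ts2 = make_training_set(matrix, cls, "absolute", n_tolerant=500, seed=4)
    assert len(ts1.positive_ids) == 100 and len(ts1.negative_ids) == 500
    assert ts1.negative_ids == ts2.negative_ids
    assert set(ts1.positive_ids).isdisjoint(ts1.negative_ids)


def test_training_set_caps_at_available_tolerant(caplog):
    labels = ["partial_high"] * 20 + ["tolerant"] * 50
    matrix = _matrix(np.random.default_rng(1).random((70, 3)))
    with caplog.at_level("WARNING"):
        ts = make_training_set(matrix, _classifications(labels), "partial", n_tolerant=10_000, seed=0)
    assert len(ts.negative_ids) == 50
    assert "only 50 available" in caplog.text


def test_training_set_requires_positives():
    matrix = _matrix(np.random.default_rng(2).random((10, 2)))
    with pytest.raises(ValueError, match="no high-confidence"):
        make_training_set(matrix, _classifications(["tolerant"] * 10), "absolute")


def test_separable_training_set_reaches_perfect_scores():
    rng = np.random.default_rng(6)
    y = np.array([1] * 120 + [0] * 480)
    X = np.column_stack([y + rng.normal(0, 0.01, len(y)), rng.random(len(y))])
    ts = TrainingSet(
        X=pd.DataFrame(X, columns=["a", "b"]), y=y,
        positive_ids=[], negative_ids=[],
    )
    model, reports, oof = crossval_train(ts, seed=0)
    winner = next(r for r in reports if r.selected)
    assert winner.mean_f1 == pytest.approx(1.0)
    assert winner.mean_roc_auc == pytest.approx(1.0)


def test_shuffled_labels_give_chance_level_auc():
    rng = np.random.default_rng(12)
    X = rng.random((5000, 5))
    y = rng.integers(0, 2, size=5000)
    ts = TrainingSet(pd.DataFrame(X), y, [], [])
    _, reports, _ = crossval_train(ts, seed=1)
    for r in reports:
        assert 0.45 <= r.mean_roc_auc <= 0.55


def test_crossval_is_deterministic_for_fixed_seed():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=600)
    X = rng.normal(y[:, None], 1.5, size=(600, 3))
    ts = TrainingSet(pd.DataFrame(X), y, [], [])
    _, r1, oof1 = crossval_train(ts, seed=9)
    _, r2, oof2 = crossval_train(ts, seed=9)
    assert [r.fold_f1 for r in r1] == [r.fold_f1 for r in r2]
    assert np.array_equal(oof1, oof2)


def brute_force_threshold(scores, labels):
    """Exhaustive sweep over all candidate thresholds (independent oracle)."""
    uniq = np.unique(scores)
    candidates = [0.0] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    best = None
    for t in candidates:
        pred = scores >= t
        if pred.sum() == 0:
            continue
        tp = (pred & (labels == 1)).sum()
        p = tp / pred.sum()
        r = tp / labels.sum()
        gap = abs(p - r)
        if best is None or gap < best[0] - 1e-12:
            best = (gap, t)
    return best


def test_threshold_spec_example():
    scores = np.array([0.9, 0.8, 0.4, 0.3])
    labels = np.array([1, 1, 1, 0])
    t, p, r = find_threshold(scores, labels)
    assert p == r == 1.0
    assert 0.3 < t < 0.4


def test_threshold_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(40):
        n = 300
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            continue
        scores = np.clip(rng.normal(0.4 + 0.2 * labels, 0.2), 0, 1)
        t, p, r = find_threshold(scores, labels)
        gap_oracle, t_oracle = brute_force_threshold(scores, labels)
        assert abs(p - r) == pytest.approx(gap_oracle, abs=1e-12)
        assert t == pytest.approx(t_oracle)


def test_precision_equals_recall_implies_fp_equals_fn():
    rng = np.random.default_rng(44)
    labels = rng.integers(0, 2, size=800)
    scores = np.clip(rng.normal(0.3 + 0.4 * labels, 0.25), 0, 1)
    t, p, r = find_threshold(scores, labels)
    pred = scores >= t
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    if p == pytest.approx(r, abs=1e-12):
        assert fp == fn


def test_update_prevalence_conserves_totals():
    rule_counts = {
        "tolerant": 7000, "absolute_high": 1000, "absolute_low": 1200,
        "partial_high": 300, "partial_low": 500,
    }
    before, after = update_prevalence(rule_counts, {"absolute": 400, "partial": 120})
    assert after.counts["absolute_high"] == 1400
    assert after.counts["absolute_low"] == 800
    assert after.si_total == before.si_total == 3000
    assert after.total == before.total
    assert after.counts["tolerant"] == before.counts["tolerant"]
    with pytest.raises(ValueError, match="cannot move"):
        update_prevalence(rule_counts, {"absolute": 1300})


def test_zero_reclassified_leaves_table_unchanged():
    rule_counts = {
        "tolerant": 90, "absolute_high": 4, "absolute_low": 3,
        "partial_high": 2, "partial_low": 1,
    }
    before, after = update_prevalence(rule_counts, {"absolute": 0, "partial": 0})
    assert before.counts == after.counts


def test_round_percent_half_up():
    assert round_percent(1, 8) == 12.5
    assert round_percent(125, 1000) == 12.5
    assert round_percent(45, 1000) == 4.5  # 4.5 exactly, stays
    assert round_percent(1, 16) == 6.3  # 6.25 rounds half-up


def test_feature_importance_ranks_signal_and_zeroes_constant():
    from lightgbm import LGBMClassifier

    rng = np.random.default_rng(15)
    n = 2000
    y = rng.integers(0, 2, size=n)
    signal = np.stack(
        [np.where(rng.random(n) < 0.5, y, rng.integers(0, 2, n)) for _ in range(5)], axis=1
    ).astype(float)
    noise = rng.random((n, 10))
    const = np.zeros((n, 1))
    X = pd.DataFrame(
        np.hstack([signal, noise, const]),
        columns=[f"s{i}" for i in range(5)] + [f"n{i}" for i in range(10)] + ["const"],
    )
    model = LGBMClassifier(random_state=0, n_jobs=1, verbosity=-1).fit(X.to_numpy(), y)
    imp = feature_importance(model, X)
    assert len(imp) == X.shape[1]
    assert set(f"s{i}" for i in range(5)) <= set(imp.index[:8])
    assert imp["const"] == 0.0
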