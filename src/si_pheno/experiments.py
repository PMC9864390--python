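"""Reusable end-to-end experiment drivers over synthetic cohorts.

These wrap the module pipeline (generate -> cohort -> events -> rules ->
features -> calibration) into the handful of summary computations the
analysis scripts and validation suites run repeatedly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import CalibrationResult, calibrate
from .cohort import select_cohort
from .config import StudyConfig
from .features import build_features, select_features
from .si_rules import classify_cohort
from .statin_events import build_profile
from .synthetic_emr import ScenarioConfig, generate_cohort


def classify_generated(records, config: StudyConfig):
    """Run eligibility, event detection and the rule engine on records."""
    entries, attrition = select_cohort(records, config)
    by_pid = {r.patient_id: r for r in records}
    profiles = {
        e.patient_id: build_profile(by_pid[e.patient_id], e, config) for e in entries
    }
    results, table = classify_cohort(entries, profiles, config)
    return entries, profiles, results, table


def rule_label_recovery(n_patients: int, seed: int) -> float:
    """Fraction of planted labels recovered by the rule engine on a
    noiseless cohort (random sign-capable events switched off)."""
    scenario = ScenarioConfig(n_patients=n_patients, seed=seed).noiseless()
    config = StudyConfig()
    records, truths = generate_cohort(scenario, config)
    _, _, results, _ = classify_generated(records, config)
    truth_by = {t.patient_id: t.planted_class for t in truths}
    hits = sum(1 for r in results if r.label == truth_by[r.patient_id])
    return hits / len(results)


@dataclasses.dataclass
class RecoveryRun:
    n: int
    latent_fraction: float
    seed: int
    rule_high_share: float
    rule_low_share: float
    post_ml_high_share: float
    target_share: float  # rule-high + latent_fraction x rule-low
    calibration: CalibrationResult

    @property
    def error_pp(self) -> float:
        return (self.post_ml_high_share - self.target_share) * 100


def prevalence_recovery(
    n_patients: int, latent_fraction: float, seed: int, k_features: int = 400
) -> RecoveryRun:
    """One full pipeline run; compares post-ML high-confidence prevalence with
    the rule-high + latent-fraction x rule-low cohort share."""
    scenario = ScenarioConfig(
        n_patients=n_patients, seed=seed, latent_si_given_low_conf=latent_fraction
    )
    config = StudyConfig()
    records, _ = generate_cohort(scenario, config)
    entries, profiles, results, table = classify_generated(records, config)
    matrix = build_features(records, entries, config)
    labels = np.array([r.label != "tolerant" for r in results], dtype=int)
    selection = select_features(matrix, labels, k=k_features)
    cal = calibrate(matrix, results, seed=seed, feature_subset=selection.selected)
    counts = dict(zip(table["label"], table["count"]))
    n = int(sum(counts.values()))
    high = counts["absolute_high"] + counts["partial_high"]
    low = counts["absolute_low"] + counts["partial_low"]
    return RecoveryRun(
        n=n,
        latent_fraction=latent_fraction,
        seed=seed,
        rule_high_share=high / n,
        rule_low_share=low / n,
        post_ml_high_share=cal.prevalence_after.high_confidence_total / n,
        target_share=(high + latent_fraction * low) / n,
        calibration=cal,
    )
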