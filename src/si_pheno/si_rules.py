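"""Five-way statin-intolerance classification from the clinical rule table.

Labels: ``tolerant`` plus absolute/partial intolerance at high/low
confidence. Absolute intolerance requires permanent statin discontinuation
(or a statin-free, non-statin-LLT-only history); partial intolerance
requires the patient to still be on statins (no >gap terminal break).

Clause evaluation order (first match wins; stronger evidence dominates):

1. ``abs_high_nonstatin_only``     - ASCVD/high-CV-risk patient only on
   non-statin LLT.
2. ``abs_high_discontinued_signs`` - permanent discontinuation plus at
   least one sign event (down-titration, low-dose use, multi-statin use,
   SAMS, intermittent dosing, documented intolerance, prior
   discontinuation).
3. ``partial_high_active_signs``   - no discontinuation of the latest
   statin plus at least one of the same sign events.
4. ``abs_low_discontinued_no_signs`` - permanent discontinuation with none
   of its listed exclusion signs (down-titration, switch, low-dose use,
   SAMS, intermittent dosing, documented intolerance).
5. ``partial_low_low_intensity``   - ASCVD/high-CV-risk patient exclusively
   on low-intensity statins with no sign events.
6. ``partial_low_titration_or_switch`` - active, non-intermittent patient
   with a down-titration or switch.

A bare switch is deliberately absent from the high-confidence sign lists:
it only reaches the low-confidence partial clause. Never-statin patients
without ASCVD/high-CV-risk tags fall through to tolerant and are flagged
``unclassifiable``.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from .statin_events import SIEventProfile

LABELS = ("tolerant", "absolute_high", "absolute_low", "partial_high", "partial_low")

HIGH_CONFIDENCE_SIGNS = frozenset(
    {
        "down_titration_same",
        "down_titration_diff",
        "low_dose",
        "multi_statin",
        "sams",
        "intermittent",
        "documented_si",
        "prior_discontinuation",
    }
)
# The low-confidence absolute clause excludes only its printed sign list.
ABS_LOW_EXCLUSION = frozenset(
    {
        "down_titration_same",
        "down_titration_diff",
        "switch",
        "low_dose",
        "sams",
        "intermittent",
        "documented_si",
    }
)
PARTIAL_LOW_INTENSITY_EXCLUSION = frozenset(
    {
        "prior_discontinuation",
        "down_titration_same",
        "down_titration_diff",
        "switch",
        "sams",
        "intermittent",
        "documented_si",
    }
)


@dataclasses.dataclass
class SIClassification:
    patient_id: str
    label: str
    fired_rule: str | None
    sign_events: frozenset[str]
    unclassifiable: bool = False


def _flags(profile: SIEventProfile) -> dict[str, bool]:
    flags = dataclasses.asdict(profile)
    flags.pop("first_down_titration")
    flags.pop("first_switch")
    return flags


def classify(
    profile: SIEventProfile,
    subgroups: set[str],
    has_statin_history: bool,
    active_statin: bool,
    patient_id: str = "",
) -> SIClassification:
    """Map one patient's event profile to the five-way intolerance label."""
    if profile.permanent_discontinuation and active_statin:
        raise ValueError(
            "contradictory inputs: permanent discontinuation with active statin use"
        )
    flags = _flags(profile)
    fired = {name for name in flags if flags.get(name)}
    high_signs = frozenset(fired & HIGH_CONFIDENCE_SIGNS)
    cv_risk = bool(subgroups & {"ascvd", "high_cv_risk"})

    if not has_statin_history:
        if cv_risk:
            return SIClassification(
                patient_id, "absolute_high", "abs_high_nonstatin_only", frozenset()
            )
        return SIClassification(
            patient_id, "tolerant", None, frozenset(), unclassifiable=True
        )

    if profile.permanent_discontinuation and high_signs:
        return SIClassification(
            patient_id, "absolute_high", "abs_high_discontinued_signs", high_signs
        )
    if active_statin and high_signs:
        return SIClassification(
            patient_id, "partial_high", "partial_high_active_signs", high_signs
        )
    if profile.permanent_discontinuation and not (fired & ABS_LOW_EXCLUSION):
        return SIClassification(
            patient_id, "absolute_low", "abs_low_discontinued_no_signs", frozenset()
        )
    if (
        active_statin
        and cv_risk
        and profile.low_intensity_only
        and not (fired & PARTIAL_LOW_INTENSITY_EXCLUSION)
    ):
        return SIClassification(
            patient_id, "partial_low", "partial_low_low_intensity", frozenset()
        )
    if (
        active_statin
        and not profile.intermittent
        and (profile.switch or profile.down_titration_same or profile.down_titration_diff)
    ):
        contributing = frozenset(
            fired & {"switch", "down_titration_same", "down_titration_diff"}
        )
        return SIClassification(
            patient_id, "partial_low", "partial_low_titration_or_switch", contributing
        )
    return SIClassification(patient_id, "tolerant", None, frozenset())


def classify_cohort(
    entries,
    profiles: dict[str, SIEventProfile],
    config=None,
) -> tuple[list[SIClassification], pd.DataFrame]:
    """Classify every cohort entry; return per-patient labels and a count table."""
    results = []
    for entry in entries:
        profile = profiles[entry.patient_id]
        active = entry.has_statin_history and not profile.permanent_discontinuation
        results.append(
            classify(
                profile,
                entry.subgroups,
                entry.has_statin_history,
                active,
                patient_id=entry.patient_id,
            )
        )
    counts = Counter(r.label for r in results)
    table = pd.DataFrame(
        {"label": list(LABELS), "count": [counts.get(lbl, 0) for lbl in LABELS]}
    )
    return results, table


def classifications_to_frame(results: list[SIClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "label": [r.label for r in results],
            "fired_rule": [r.fired_rule or "" for r in results],
            "sign_events": ["|".join(sorted(r.sign_events)) for r in results],
            "unclassifiable": [r.unclassifiable for r in results],
        }
    )
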