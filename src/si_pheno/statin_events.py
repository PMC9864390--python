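"""Statin exposure histories and the seven intolerance signal events.

Events are assessed on each patient's statin prescriptions within
``[lookback_start, study_end)``:

* down-titration (same molecule: strictly lower dose; different molecule:
  strictly lower intensity band) between consecutive scripts,
* switch (molecule change at unchanged intensity) / multi-statin use
  (>= 2 molecules with >= 2 molecule-change transitions, i.e. alternating
  or concurrent use rather than a single clean switch),
* permanent discontinuation (coverage end of the last script more than
  ``gap_days`` before study end) and prior discontinuation (an interior
  refill gap exceeding ``gap_days`` followed by resumption),
* intermittent dosing, operationalized as a medication-possession ratio
  below ``mpr_threshold`` over >= 3 scripts while still on therapy,
* exclusive low-dose use (every script at or below the molecule's lowest
  marketed daily dose),
* a structured documented-intolerance note, and
* SAMS diagnosis codes in the lookback window.

Script coverage ends at ``date + days_supplied`` (default 30 days), so
ordinary refill jitter never reads as discontinuation.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

from .config import StudyConfig, matches_any_prefix
from .cohort import CohortEntry
from .data_model import PatientRecord

INTENSITY_ORDER = {"low": 0, "moderate": 1, "high": 2}


class IntensityMap:
    """Dose-band -> intensity class and lowest marketed dose per molecule."""

    def __init__(self, spec: dict[str, dict]):
        self._spec = spec

    @classmethod
    def from_config(cls, config: StudyConfig) -> "IntensityMap":
        return cls(config.intensity_spec)

    def molecules(self) -> list[str]:
        return list(self._spec)

    def atc(self, molecule: str) -> str:
        return self._entry(molecule)["atc"]

    def _entry(self, molecule: str) -> dict:
        try:
            return self._spec[molecule]
        except KeyError:
            raise KeyError(f"unknown statin molecule: {molecule!r}") from None

    def intensity(self, molecule: str, dose_mg: float) -> str:
        entry = self._entry(molecule)
        low_max = entry.get("low_max")
        if low_max is not None and dose_mg <= low_max:
            return "low"
        if dose_mg <= entry["moderate_max"]:
            return "moderate"
        return "high"

    def lowest_dose(self, molecule: str) -> float:
        return float(self._entry(molecule)["lowest_dose"])


@dataclasses.dataclass(frozen=True)
class StatinScript:
    date: dt.date
    molecule: str
    dose_mg: float
    intensity: str
    days_supplied: int


@dataclasses.dataclass
class StatinExposure:
    patient_id: str
    scripts: list[StatinScript]

    @property
    def span_start(self) -> dt.date | None:
        return self.scripts[0].date if self.scripts else None

    @property
    def span_end(self) -> dt.date | None:
        return self.scripts[-1].date if self.scripts else None

    def __len__(self) -> int:
        return len(self.scripts)


@dataclasses.dataclass
class SIEventProfile:
    """Per-patient booleans for the intolerance signal events."""

    down_titration_same: bool = False
    down_titration_diff: bool = False
    switch: bool = False
    multi_statin: bool = False
    permanent_discontinuation: bool = False
    prior_discontinuation: bool = False
    intermittent: bool = False
    low_dose: bool = False
    low_intensity_only: bool = False
    documented_si: bool = False
    sams: bool = False
    first_down_titration: tuple[StatinScript, StatinScript] | None = None
    first_switch: tuple[StatinScript, StatinScript] | None = None

    def sign_events(self) -> set[str]:
        """Names of the high-confidence sign events that fired."""
        signs = {
            "down_titration_same": self.down_titration_same,
            "down_titration_diff": self.down_titration_diff,
            "low_dose": self.low_dose,
            "multi_statin": self.multi_statin,
            "sams": self.sams,
            "intermittent": self.intermittent,
            "documented_si": self.documented_si,
            "prior_discontinuation": self.prior_discontinuation,
        }
        return {name for name, fired in signs.items() if fired}


_STATIN_NAMES = (
    "simvastatin", "lovastatin", "pravastatin", "fluvastatin",
    "atorvastatin", "rosuvastatin", "pitavastatin",
)


def normalize_statin_molecule(atc: str, molecule: str) -> str | None:
    """Statin component of a plain (C10AA) or fixed-combination (C10B) product."""
    molecule = molecule.lower()
    if atc.startswith("C10AA"):
        for name in _STATIN_NAMES:
            if name in molecule:
                return name
        return molecule
    if atc.startswith(("C10BA", "C10BX")):
        for name in _STATIN_NAMES:
            if name in molecule:
                return name
    return None


def build_exposure(
    record: PatientRecord, entry: CohortEntry, config: StudyConfig
) -> StatinExposure:
    """Statin scripts within [lookback_start, study_end), intensity-annotated."""
    imap = IntensityMap.from_config(config)
    scripts = []
    for rx in record.prescriptions:
        if not (entry.lookback_start <= rx.date < config.study_end):
            continue
        molecule = normalize_statin_molecule(rx.atc, rx.molecule)
        if molecule is None or rx.dose_mg is None:
            continue
        scripts.append(
            StatinScript(
                date=rx.date,
                molecule=molecule,
                dose_mg=float(rx.dose_mg),
                intensity=imap.intensity(molecule, float(rx.dose_mg)),
                days_supplied=rx.days_supplied or config.default_days_supplied,
            )
        )
    scripts.sort(key=lambda s: (s.date, s.molecule, s.dose_mg))
    return StatinExposure(patient_id=record.patient_id, scripts=scripts)


def _consecutive_pairs(exposure: StatinExposure):
    return zip(exposure.scripts, exposure.scripts[1:])


def detect_down_titration(
    exposure: StatinExposure,
) -> tuple[bool, bool, tuple[StatinScript, StatinScript] | None]:
    """Same-molecule dose drop or cross-molecule intensity drop (consecutive pair)."""
    same = diff = False
    first = None
    for a, b in _consecutive_pairs(exposure):
        hit = False
        if a.molecule == b.molecule and b.dose_mg < a.dose_mg:
            same, hit = True, True
        elif a.molecule != b.molecule and (
            INTENSITY_ORDER[b.intensity] < INTENSITY_ORDER[a.intensity]
        ):
            diff, hit = True, True
        if hit and first is None:
            first = (a, b)
    return same, diff, first


def detect_switch(
    exposure: StatinExposure,
) -> tuple[bool, bool, tuple[StatinScript, StatinScript] | None]:
    """Intensity-preserving molecule change; multi-statin = alternating use."""
    switch = False
    first = None
    transitions = 0
    for a, b in _consecutive_pairs(exposure):
        if a.molecule != b.molecule:
            transitions += 1
            if INTENSITY_ORDER[b.intensity] == INTENSITY_ORDER[a.intensity]:
                switch = True
                if first is None:
                    first = (a, b)
    n_molecules = len({s.molecule for s in exposure.scripts})
    multi = n_molecules >= 2 and transitions >= 2
    return switch, multi, first


def _coverage_end(script: StatinScript) -> dt.date:
    return script.date + dt.timedelta(days=script.days_supplied)


def detect_discontinuation(
    exposure: StatinExposure, config: StudyConfig
) -> tuple[bool, bool]:
    """(permanent, prior) discontinuation from refill gaps > gap_days."""
    if not exposure.scripts:
        return False, False
    terminal_gap = (config.study_end - _coverage_end(exposure.scripts[-1])).days
    permanent = terminal_gap > config.gap_days
    prior = any(
        (b.date - _coverage_end(a)).days > config.gap_days
        for a, b in _consecutive_pairs(exposure)
    )
    return permanent, prior


def detect_intermittent(exposure: StatinExposure, config: StudyConfig) -> bool:
    """MPR below threshold over >= 3 scripts while not permanently discontinued."""
    if len(exposure) < config.min_scripts_for_mpr:
        return False
    permanent, _ = detect_discontinuation(exposure, config)
    if permanent:
        return False
    total_supplied = sum(s.days_supplied for s in exposure.scripts)
    span = (exposure.span_end - exposure.span_start).days + exposure.scripts[-1].days_supplied
    return total_supplied / span < config.mpr_threshold


def detect_low_dose(exposure: StatinExposure, imap: IntensityMap) -> bool:
    """Exclusive low-dose use: every script at <= the lowest marketed dose."""
    if not exposure.scripts:
        raise ValueError("low-dose detection requires a non-empty exposure")
    return all(s.dose_mg <= imap.lowest_dose(s.molecule) for s in exposure.scripts)


def detect_low_intensity_only(exposure: StatinExposure) -> bool:
    if not exposure.scripts:
        return False
    return all(s.intensity == "low" for s in exposure.scripts)


def detect_sams(record: PatientRecord, entry: CohortEntry, config: StudyConfig) -> bool:
    """SAMS diagnosis within the lookback window [lookback_start, index]."""
    prefixes = config.code_prefixes("sams")
    window_end = entry.index_date + dt.timedelta(days=1)
    return any(
        matches_any_prefix(d.icd10, prefixes)
        and entry.lookback_start <= d.date < window_end
        for d in record.diagnoses
    )


def build_profile(
    record: PatientRecord, entry: CohortEntry, config: StudyConfig
) -> SIEventProfile:
    """Run all detectors over one patient's lookback window."""
    exposure = build_exposure(record, entry, config)
    profile = SIEventProfile()
    profile.documented_si = record.documented_si_note
    profile.sams = detect_sams(record, entry, config)
    if exposure.scripts:
        imap = IntensityMap.from_config(config)
        same, diff, first_dt = detect_down_titration(exposure)
        profile.down_titration_same = same
        profile.down_titration_diff = diff
        profile.first_down_titration = first_dt
        switch, multi, first_sw = detect_switch(exposure)
        profile.switch = switch
        profile.multi_statin = multi
        profile.first_switch = first_sw
        permanent, prior = detect_discontinuation(exposure, config)
        profile.permanent_discontinuation = permanent
        profile.prior_discontinuation = prior
        profile.intermittent = detect_intermittent(exposure, config)
        profile.low_dose = detect_low_dose(exposure, imap)
        profile.low_intensity_only = detect_low_intensity_only(exposure)
    return profile
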