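"""Synthetic outpatient EMR cohorts with planted statin-intolerance phenotypes.

The generator emits the same three-table EMR structure the analysis
consumes, with a hidden truth channel per patient:

* ``planted_class`` - one of the five rule labels; each class is realized
  by a prescription/diagnosis trajectory that the rule engine maps back to
  that class (down-titration, switch, discontinuation, intermittent dosing,
  low-dose or low-intensity regimens, SAMS codes, non-statin-only use).
* ``latent_intolerant`` - whether the patient is truly intolerant. All
  high-confidence patients are; low-confidence patients are with
  probability ``latent_si_given_low_conf``; tolerant patients are not.

Truly intolerant patients draw their *feature* signal (myalgia and cramp
codes, fibrate co-prescription, physician-visit counts) at rate-ratio-scaled
frequencies, but low-confidence patients never receive deterministic sign
events - that is exactly the population the supervised-learning step has to
rescue. Background comorbidity and pure-noise diagnosis codes are planted at
class-independent rates. Because incidental muscle-symptom codes are real
sign events, they occasionally flip a rule label (e.g. a tolerant patient
with a chance myalgia code reads as partial intolerance); the ``noiseless``
scenario switches those baselines off, making label recovery exact.

All randomness flows from one seed; each patient's substream is derived
from ``(seed, patient_index)``, so cohorts are byte-identical per seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .config import StudyConfig
from .data_model import DiagnosisEvent, PatientRecord, PrescriptionEvent
from .si_rules import LABELS
from .statin_events import IntensityMap

DAY = dt.timedelta(days=1)

# market-share-like molecule weights for tolerant/background regimens
_MOLECULE_WEIGHTS = {
    "simvastatin": 0.50,
    "atorvastatin": 0.37,
    "pravastatin": 0.05,
    "rosuvastatin": 0.03,
    "fluvastatin": 0.03,
    "lovastatin": 0.01,
    "pitavastatin": 0.01,
}
_MODERATE_DOSES = {
    "simvastatin": [20, 40],
    "atorvastatin": [10, 20],
    "pravastatin": [40],
    "rosuvastatin": [5, 10],
    "fluvastatin": [80],
    "lovastatin": [40],
    "pitavastatin": [2, 4],
}

_SAMS_PLANT_CODES = ["M79.1", "R25.2", "M60.9", "G72.0"]
_ASCVD_CODES = ["I25.1", "I20.0", "I21.9", "I63.9", "I70.2"]
_HCVR_CODES = ["E11.9", "E10.9"]
_HCHOL_CODES = ["E78.0", "E78.2", "E78.4", "E78.5"]
_COMORBIDITY_RATES = {
    "E66.0": 0.095,  # obesity
    "E03.9": 0.089,  # hypothyroidism
    "E55.9": 0.180,  # vitamin D deficiency
    "N18.3": 0.047,  # chronic kidney disease
    "K29.7": 0.140,  # gastritis
}
_VISIT_FILLER_CODE = "Z76.0"


def _default_class_mix() -> dict[str, float]:
    return {
        "tolerant": 0.757,
        "absolute_high": 0.064,
        "absolute_low": 0.094,
        "partial_high": 0.028,
        "partial_low": 0.057,
    }


def _default_signal_effects() -> dict[str, float]:
    return {"myalgia": 2.2, "cramps": 1.9, "fibrate_use": 5.0, "visit_count": 1.3}


def _default_baseline_rates() -> dict[str, float]:
    # per-lookback probabilities (visit_count is a Poisson mean over the lookback)
    return {"myalgia": 0.019, "cramps": 0.022, "fibrate_use": 0.011, "visit_count": 16.0}


@dataclasses.dataclass
class ScenarioConfig:
    """Knobs of one synthetic cohort scenario."""

    n_patients: int = 1000
    seed: int = 0
    class_mix: dict[str, float] = dataclasses.field(default_factory=_default_class_mix)
    latent_si_given_low_conf: float = 0.5
    signal_effects: dict[str, float] = dataclasses.field(
        default_factory=_default_signal_effects
    )
    baseline_rates: dict[str, float] = dataclasses.field(
        default_factory=_default_baseline_rates
    )
    n_noise_features: int = 30
    noise_rate: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.class_mix) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in mix: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        if not all(0 <= p <= 1 for p in self.class_mix.values()):
            raise ValueError("class probabilities must lie in [0, 1]")
        if not 0 <= self.latent_si_given_low_conf <= 1:
            raise ValueError("latent_si_given_low_conf must lie in [0, 1]")
        if any(r <= 0 for r in self.signal_effects.values()):
            raise ValueError("signal rate ratios must be positive")

    def noiseless(self) -> "ScenarioConfig":
        """Variant with random sign-capable events switched off entirely."""
        rates = dict(self.baseline_rates)
        for name in ("myalgia", "cramps", "fibrate_use"):
            rates[name] = 0.0
        return dataclasses.replace(self, baseline_rates=rates, n_noise_features=0)


@dataclasses.dataclass
class GroundTruth:
    patient_id: str
    planted_class: str
    latent_intolerant: bool


def _noise_code_pool(n: int) -> list[str]:
    return [f"{'JKLZ'[i % 4]}{30 + i // 4:02d}.0" for i in range(n)]


def _rand_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    """Uniform date in the half-open interval [start, end)."""
    span = (end - start).days
    return start + int(rng.integers(0, max(span, 1))) * DAY


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    p = np.asarray([weights[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=p / p.sum()))]


def _steady_dates(
    rng: np.random.Generator,
    last: dt.date,
    n: int,
    lo: int = 28,
    hi: int = 36,
    floor: dt.date | None = None,
) -> list[dt.date]:
    """n script dates ending at `last`, spaced by refill intervals in [lo, hi)."""
    dates = [last]
    for _ in range(n - 1):
        dates.append(dates[-1] - int(rng.integers(lo, hi)) * DAY)
    if floor is not None:
        dates = [d for d in dates if d >= floor]
    return sorted(dates)


class _Trajectory:
    def __init__(self) -> None:
        self.prescriptions: list[PrescriptionEvent] = []
        self.diagnoses: list[DiagnosisEvent] = []
        self.documented = False
        self.forced_subgroup: str | None = None
        self.index_date: dt.date | None = None

    def add_statin(self, imap: IntensityMap, dates, molecule: str, dose: float) -> None:
        for d in dates:
            self.prescriptions.append(
                PrescriptionEvent(
                    date=d,
                    atc=imap.atc(molecule),
                    molecule=molecule,
                    dose_mg=float(dose),
                    days_supplied=30,
                )
            )


def _active_last_date(rng: np.random.Generator, study: StudyConfig) -> dt.date:
    # late enough that the terminal gap stays <= gap_days
    lo = study.study_end - dt.timedelta(days=study.gap_days - 20)
    hi = study.study_end - dt.timedelta(days=14)
    return _rand_date(rng, lo, hi)


def _discontinued_last_date(rng: np.random.Generator, study: StudyConfig) -> dt.date:
    lo = study.study_start + dt.timedelta(days=360)
    hi = study.study_end - dt.timedelta(days=study.gap_days + 60)
    return _rand_date(rng, lo, hi)


def plant_trajectory(
    planted_class: str,
    rng: np.random.Generator,
    study: StudyConfig,
    imap: IntensityMap,
) -> _Trajectory:
    """Prescription/diagnosis skeleton realizing one planted rule label."""
    traj = _Trajectory()
    floor = study.study_start

    def moderate_regimen(last: dt.date, n: int) -> None:
        mol = _weighted_choice(rng, _MOLECULE_WEIGHTS)
        dose = _MODERATE_DOSES[mol][int(rng.integers(len(_MODERATE_DOSES[mol])))]
        if dose <= imap.lowest_dose(mol):  # keep clear of the low-dose sign
            dose = _MODERATE_DOSES[mol][-1]
        traj.add_statin(imap, _steady_dates(rng, last, n, floor=floor), mol, dose)

    if planted_class == "tolerant":
        moderate_regimen(_active_last_date(rng, study), int(rng.integers(5, 25)))

    elif planted_class == "absolute_low":
        moderate_regimen(_discontinued_last_date(rng, study), int(rng.integers(5, 16)))

    elif planted_class == "absolute_high":
        variant = _weighted_choice(
            rng,
            {
                "nonstatin_only": 0.25,
                "sams": 0.20,
                "down_titration": 0.15,
                "multi_statin": 0.10,
                "low_dose": 0.10,
                "prior_discontinuation": 0.10,
                "documented": 0.10,
            },
        )
        if variant == "nonstatin_only":
            last = _active_last_date(rng, study)
            for d in _steady_dates(rng, last, int(rng.integers(8, 20)), floor=floor):
                traj.prescriptions.append(
                    PrescriptionEvent(d, "C10AX09", "ezetimibe", 10.0, 30)
                )
            traj.forced_subgroup = (
                "ascvd" if rng.random() < 0.7 else "high_cv_risk"
            )
            traj.index_date = last
            return traj
        last = _discontinued_last_date(rng, study)
        n = int(rng.integers(5, 16))
        if variant == "down_titration":
            mol, hi_d, lo_d = [
                ("atorvastatin", 40, 20),
                ("simvastatin", 40, 20),
                ("simvastatin", 20, 10),
            ][int(rng.choice(3, p=[0.55, 0.30, 0.15]))]
            dates = _steady_dates(rng, last, n, floor=floor)
            k = len(dates) - int(rng.integers(1, 3))
            traj.add_statin(imap, dates[:k], mol, hi_d)
            traj.add_statin(imap, dates[k:], mol, lo_d)
        elif variant == "multi_statin":
            dates = _steady_dates(rng, last, max(n, 6), floor=floor)
            third = max(len(dates) // 3, 1)
            traj.add_statin(imap, dates[:third], "simvastatin", 20)
            traj.add_statin(imap, dates[third : 2 * third], "atorvastatin", 20)
            traj.add_statin(imap, dates[2 * third :], "simvastatin", 20)
        elif variant == "low_dose":
            mol = _weighted_choice(rng, _MOLECULE_WEIGHTS)
            traj.add_statin(
                imap, _steady_dates(rng, last, n, floor=floor), mol, imap.lowest_dose(mol)
            )
        elif variant == "prior_discontinuation":
            # resumption block must be late enough that the interior gap and
            # the first block both fit after the study start
            late_lo = study.study_start + dt.timedelta(days=700)
            last = _rand_date(rng, late_lo, study.study_end - dt.timedelta(days=study.gap_days + 60))
            dates2 = _steady_dates(rng, last, int(rng.integers(2, 5)), floor=floor)
            gap = int(rng.integers(study.gap_days + 40, study.gap_days + 220))
            last1 = dates2[0] - gap * DAY
            dates1 = [d for d in _steady_dates(rng, last1, int(rng.integers(3, 8))) if d >= floor]
            mol = _weighted_choice(rng, _MOLECULE_WEIGHTS)
            dose = _MODERATE_DOSES[mol][-1]
            traj.add_statin(imap, dates1 + dates2, mol, dose)
        else:  # sams or documented over a plain discontinued regimen
            moderate_regimen(last, n)
            if variant == "sams":
                lookback_start = max(floor, last - dt.timedelta(days=study.lookback_days))
                for _ in range(int(rng.integers(1, 3))):
                    code = _SAMS_PLANT_CODES[int(rng.integers(len(_SAMS_PLANT_CODES)))]
                    traj.diagnoses.append(
                        DiagnosisEvent(_rand_date(rng, lookback_start, last + DAY), code)
                    )
            else:
                traj.documented = True
        traj.index_date = last

    elif planted_class == "partial_high":
        variant = _weighted_choice(
            rng,
            {
                "sams": 0.30,
                "down_titration": 0.20,
                "multi_statin": 0.10,
                "low_dose": 0.10,
                "intermittent": 0.15,
                "prior_discontinuation": 0.10,
                "documented": 0.05,
            },
        )
        last = _active_last_date(rng, study)
        n = int(rng.integers(6, 22))
        if variant == "down_titration":
            mol, hi_d, lo_d = [
                ("atorvastatin", 40, 20),
                ("simvastatin", 40, 20),
                ("simvastatin", 20, 10),
            ][int(rng.choice(3, p=[0.55, 0.30, 0.15]))]
            dates = _steady_dates(rng, last, n, floor=floor)
            k = int(rng.integers(len(dates) // 3, 2 * len(dates) // 3 + 1))
            traj.add_statin(imap, dates[:k], mol, hi_d)
            traj.add_statin(imap, dates[k:], mol, lo_d)
        elif variant == "multi_statin":
            dates = _steady_dates(rng, last, n, floor=floor)
            third = max(len(dates) // 3, 1)
            traj.add_statin(imap, dates[:third], "simvastatin", 20)
            traj.add_statin(imap, dates[third : 2 * third], "atorvastatin", 20)
            traj.add_statin(imap, dates[2 * third :], "simvastatin", 20)
        elif variant == "low_dose":
            mol = _weighted_choice(rng, _MOLECULE_WEIGHTS)
            traj.add_statin(
                imap, _steady_dates(rng, last, n, floor=floor), mol, imap.lowest_dose(mol)
            )
        elif variant == "intermittent":
            dates = _steady_dates(rng, last, int(rng.integers(4, 8)), lo=75, hi=151, floor=floor)
            mol = _weighted_choice(rng, _MOLECULE_WEIGHTS)
            traj.add_statin(imap, dates, mol, _MODERATE_DOSES[mol][-1])
        elif variant == "prior_discontinuation":
            dates2 = _steady_dates(rng, last, int(rng.integers(4, 8)), floor=floor)
            gap = int(rng.integers(study.gap_days + 40, study.gap_days + 220))
            last1 = dates2[0] - gap * DAY
            dates1 = [d for d in _steady_dates(rng, last1, int(rng.integers(3, 8))) if d >= floor]
            mol = _weighted_choice(rng, _MOLECULE_WEIGHTS)
            traj.add_statin(imap, dates1 + dates2, mol, _MODERATE_DOSES[mol][-1])
        else:  # sams or documented over a plain active regimen
            moderate_regimen(last, n)
            if variant == "sams":
                lookback_start = max(floor, last - dt.timedelta(days=study.lookback_days))
                for _ in range(int(rng.integers(1, 3))):
                    code = _SAMS_PLANT_CODES[int(rng.integers(len(_SAMS_PLANT_CODES)))]
                    traj.diagnoses.append(
                        DiagnosisEvent(_rand_date(rng, lookback_start, last + DAY), code)
                    )
            else:
                traj.documented = True
        traj.index_date = last

    elif planted_class == "partial_low":
        last = _active_last_date(rng, study)
        if rng.random() < 0.5:  # exclusive low-intensity regimen, above lowest dose
            mol, dose = [("pravastatin", 20), ("fluvastatin", 40)][int(rng.integers(2))]
            traj.add_statin(
                imap, _steady_dates(rng, last, int(rng.integers(6, 22)), floor=floor), mol, dose
            )
            traj.forced_subgroup = "ascvd" if rng.random() < 0.7 else "high_cv_risk"
        else:  # one clean intensity-preserving switch
            mol_a, dose_a, mol_b, dose_b = [
                ("simvastatin", 20, "atorvastatin", 20),
                ("simvastatin", 40, "atorvastatin", 20),
            ][int(rng.choice(2, p=[0.6, 0.4]))]
            dates = _steady_dates(rng, last, int(rng.integers(8, 22)), floor=floor)
            k = int(rng.integers(len(dates) // 3, 2 * len(dates) // 3 + 1))
            traj.add_statin(imap, dates[:k], mol_a, dose_a)
            traj.add_statin(imap, dates[k:], mol_b, dose_b)
        traj.index_date = last

    else:
        raise ValueError(f"unknown planted class: {planted_class!r}")

    if traj.index_date is None:
        traj.index_date = max(p.date for p in traj.prescriptions)
    return traj


def _plant_background(
    traj: _Trajectory,
    rng: np.random.Generator,
    scenario: ScenarioConfig,
    study: StudyConfig,
    latent: bool,
    noise_pool: list[str],
) -> None:
    index = traj.index_date
    lookback_start = max(study.study_start, index - dt.timedelta(days=study.lookback_days))
    window_end = index + DAY

    def effect(name: str) -> float:
        return scenario.signal_effects.get(name, 1.0) if latent else 1.0

    # physician visits (repeat-prescription encounters with no new diagnosis).
    # Prescription/diagnosis dates are themselves visits, so the background
    # mean is chosen so that the *total* visit count shows the configured
    # rate ratio for truly intolerant patients.
    traj_dates = {p.date for p in traj.prescriptions} | {d.date for d in traj.diagnoses}
    eff_v = effect("visit_count")
    bg_mean = scenario.baseline_rates["visit_count"] * eff_v + (eff_v - 1.0) * len(traj_dates)
    n_visits = int(rng.poisson(max(bg_mean, 0.0)))
    for _ in range(n_visits):
        traj.diagnoses.append(
            DiagnosisEvent(_rand_date(rng, lookback_start, window_end), _VISIT_FILLER_CODE)
        )

    for name, code in (("myalgia", "M79.1"), ("cramps", "R25.2")):
        p = min(1.0, scenario.baseline_rates[name] * effect(name))
        if rng.random() < p:
            for _ in range(1 + int(rng.poisson(0.4))):
                traj.diagnoses.append(
                    DiagnosisEvent(_rand_date(rng, lookback_start, window_end), code)
                )

    p_fib = min(1.0, scenario.baseline_rates["fibrate_use"] * effect("fibrate_use"))
    if rng.random() < p_fib:
        k = 1 + int(rng.integers(0, 3))
        span = max((window_end - lookback_start).days, k)
        offsets = rng.choice(span, size=k, replace=False)  # distinct script dates
        for off in offsets:
            traj.prescriptions.append(
                PrescriptionEvent(
                    lookback_start + int(off) * DAY, "C10AB05", "fenofibrate", 250.0, 30
                )
            )

    for code, rate in _COMORBIDITY_RATES.items():
        if rng.random() < rate:
            traj.diagnoses.append(
                DiagnosisEvent(_rand_date(rng, lookback_start, window_end), code)
            )
    for code in noise_pool:
        if rng.random() < scenario.noise_rate:
            traj.diagnoses.append(
                DiagnosisEvent(_rand_date(rng, lookback_start, window_end), code)
            )


def generate_cohort(
    scenario: ScenarioConfig, study: StudyConfig | None = None
) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Generate one cohort; every patient satisfies the eligibility criteria."""
    study = study or StudyConfig()
    imap = IntensityMap.from_config(study)
    master = np.random.default_rng(scenario.seed)
    labels = list(LABELS)
    mix = np.asarray([scenario.class_mix.get(lbl, 0.0) for lbl in labels])
    classes = master.choice(len(labels), size=scenario.n_patients, p=mix)
    noise_pool = _noise_code_pool(scenario.n_noise_features)

    subgroup_weights = {"ascvd": 0.56, "high_cv_risk": 0.21, "hypercholesterolemia": 0.23}
    subgroup_codes = {
        "ascvd": _ASCVD_CODES,
        "high_cv_risk": _HCVR_CODES,
        "hypercholesterolemia": _HCHOL_CODES,
    }

    records: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    for i in range(scenario.n_patients):
        rng = np.random.default_rng([scenario.seed, i])
        planted = labels[classes[i]]
        if planted in ("absolute_high", "partial_high"):
            latent = True
        elif planted in ("absolute_low", "partial_low"):
            latent = bool(rng.random() < scenario.latent_si_given_low_conf)
        else:
            latent = False

        traj = plant_trajectory(planted, rng, study, imap)
        _plant_background(traj, rng, scenario, study, latent, noise_pool)

        subgroup = traj.forced_subgroup or _weighted_choice(rng, subgroup_weights)
        codes = subgroup_codes[subgroup]
        code = codes[int(rng.integers(len(codes)))]
        # one qualifying diagnosis inside the selection window doubles as the
        # guaranteed consultation; optionally one earlier in the record
        traj.diagnoses.append(
            DiagnosisEvent(_rand_date(rng, study.selection_start, study.selection_end), code)
        )
        if rng.random() < 0.6:
            traj.diagnoses.append(
                DiagnosisEvent(
                    _rand_date(rng, study.study_start, traj.index_date + DAY), code
                )
            )

        pid = f"P{i:06d}"
        age = int(rng.integers(40, 91))
        gender = ("female", "male", "unspecified")[
            int(rng.choice(3, p=[0.443, 0.551, 0.006]))
        ]
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=traj.index_date.year - age,
                gender=gender,
                diagnoses=traj.diagnoses,
                prescriptions=traj.prescriptions,
                documented_si_note=traj.documented,
            )
        )
        truths.append(GroundTruth(pid, planted, latent))
    return records, truths


def truths_to_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in truths],
            "planted_class": [t.planted_class for t in truths],
            "latent_intolerant": [t.latent_intolerant for t in truths],
        }
    )
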