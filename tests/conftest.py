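import datetime as dt

import pytest

from si_pheno import StudyConfig
from si_pheno.cohort import CohortEntry
from si_pheno.data_model import DiagnosisEvent, PatientRecord, PrescriptionEvent
from si_pheno.synthetic_emr import ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


def make_statin_rx(date, molecule="simvastatin", dose=20.0, atc="C10AA01", days=30):
    return PrescriptionEvent(
        date=date, atc=atc, molecule=molecule, dose_mg=dose, days_supplied=days
    )


def make_patient(pid="P1", birth_year=1950, gender="male", dx=(), rx=(), note=False):
    return PatientRecord(
        patient_id=pid,
        birth_year=birth_year,
        gender=gender,
        diagnoses=list(dx),
        prescriptions=list(rx),
        documented_si_note=note,
    )


def entry_for(record: PatientRecord, config: StudyConfig, has_statin=True):
    """Cohort entry anchored at the patient's latest statin script."""
    statin_dates = [p.date for p in record.prescriptions if p.atc.startswith("C10AA")]
    index = max(statin_dates) if statin_dates else max(p.date for p in record.prescriptions)
    return CohortEntry(
        patient_id=record.patient_id,
        index_date=index,
        lookback_start=max(config.study_start, index - dt.timedelta(days=config.lookback_days)),
        subgroups={"ascvd"},
        age_at_index=index.year - record.birth_year,
        has_statin_history=has_statin,
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """2000-patient cohort with random sign-capable events switched off."""
    scenario = ScenarioConfig(n_patients=2000, seed=11).noiseless()
    records, truths = generate_cohort(scenario, StudyConfig())
    return records, truths


@pytest.fixture(scope="session")
def small_noisy_cohort():
    records, truths = generate_cohort(
        ScenarioConfig(n_patients=3000, seed=42), StudyConfig()
    )
    return records, truths
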