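import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from si_pheno import StudyConfig
from si_pheno.data_model import DiagnosisEvent, PrescriptionEvent
from si_pheno.statin_events import (
    IntensityMap,
    StatinExposure,
    StatinScript,
    build_exposure,
    detect_discontinuation,
    detect_down_titration,
    detect_intermittent,
    detect_low_dose,
    detect_sams,
    detect_switch,
)

from .conftest import entry_for, make_patient, make_statin_rx

D = dt.date


def _imap():
    return IntensityMap.from_config(StudyConfig())


def scripts(*specs, start=D(2019, 1, 1), step=30):
    """Build an exposure from (molecule, dose) pairs spaced `step` days apart."""
    imap = _imap()
    out = []
    day = start
    for mol, dose in specs:
        out.append(
            StatinScript(day, mol, float(dose), imap.intensity(mol, dose), 30)
        )
        day += dt.timedelta(days=step)
    return StatinExposure("T", out)


# --- exposure construction -------------------------------------------------

def test_non_statin_only_patient_has_empty_exposure(config):
    rec = make_patient(
        rx=[PrescriptionEvent(D(2019, 5, 1), "C10AX09", "ezetimibe", 10, 30)],
        dx=[DiagnosisEvent(D(2019, 5, 1), "I25.1")],
    )
    entry = entry_for(rec, config, has_statin=False)
    assert build_exposure(rec, entry, config).scripts == []


def test_lookback_window_boundary_is_half_open(config):
    rx_at = make_statin_rx(D(2019, 10, 1))
    rec = make_patient(rx=[rx_at])
    entry = entry_for(rec, config)
    before = entry.lookback_start - dt.timedelta(days=1)
    rec2 = make_patient(
        rx=[rx_at, make_statin_rx(before), make_statin_rx(entry.lookback_start)]
    )
    exposure = build_exposure(rec2, entry, config)
    assert [s.date for s in exposure.scripts] == [entry.lookback_start, D(2019, 10, 1)]


def test_fixed_combination_contributes_statin_component(config):
    rec = make_patient(
        rx=[
            make_statin_rx(D(2019, 8, 1)),
            PrescriptionEvent(
                D(2019, 9, 1), "C10BA02", "simvastatin/ezetimibe", 20, 30
            ),
        ]
    )
    entry = entry_for(rec, config)
    exposure = build_exposure(rec, entry, config)
    assert [s.molecule for s in exposure.scripts] == ["simvastatin", "simvastatin"]


# --- down-titration / switch ----------------------------------------------

def test_same_molecule_dose_drop_is_down_titration():
    same, diff, first = detect_down_titration(
        scripts(("atorvastatin", 40), ("atorvastatin", 20))
    )
    assert same and not diff
    assert (first[0].dose_mg, first[1].dose_mg) == (40, 20)


def test_intensity_preserving_molecule_change_is_switch_not_down_titration():
    exposure = scripts(("simvastatin", 20), ("atorvastatin", 20))  # moderate->moderate
    same, diff, _ = detect_down_titration(exposure)
    assert not same and not diff
    switch, multi, first = detect_switch(exposure)
    assert switch and not multi
    assert first[0].molecule == "simvastatin" and first[1].molecule == "atorvastatin"


def test_up_titration_fires_nothing():
    exposure = scripts(("atorvastatin", 20), ("atorvastatin", 40))
    assert detect_down_titration(exposure)[:2] == (False, False)
    assert detect_switch(exposure)[:2] == (False, False)


def test_cross_molecule_intensity_drop_is_down_titration():
    # atorvastatin 40 is high intensity, simvastatin 20 moderate
    same, diff, _ = detect_down_titration(
        scripts(("atorvastatin", 40), ("simvastatin", 20))
    )
    assert diff and not same


def test_alternating_molecules_are_multi_statin():
    exposure = scripts(("simvastatin", 20), ("atorvastatin", 20), ("simvastatin", 20))
    switch, multi, _ = detect_switch(exposure)
    assert multi and switch
    assert len({s.molecule for s in exposure.scripts}) == 2


def test_single_molecule_never_switch_or_multi():
    exposure = scripts(("simvastatin", 20), ("simvastatin", 20), ("simvastatin", 20))
    assert detect_switch(exposure)[:2] == (False, False)


@settings(max_examples=200, deadline=None)
@given(
    mol_a=st.sampled_from(["simvastatin", "atorvastatin", "rosuvastatin", "pravastatin"]),
    dose_a=st.sampled_from([10, 20, 40]),
    mol_b=st.sampled_from(["simvastatin", "atorvastatin", "rosuvastatin", "pravastatin"]),
    dose_b=st.sampled_from([10, 20, 40]),
)
def test_pairwise_events_mutually_exclusive(mol_a, dose_a, mol_b, dose_b):
    """For one consecutive pair, down-titration, switch and up-titration exclude
    each other."""
    exposure = scripts((mol_a, dose_a), (mol_b, dose_b))
    same, diff, _ = detect_down_titration(exposure)
    switch = detect_switch(exposure)[0]
    imap = _imap()
    ia = imap.intensity(mol_a, dose_a)
    ib = imap.intensity(mol_b, dose_b)
    up = (mol_a == mol_b and dose_b > dose_a) or (
        mol_a != mol_b
        and ["low", "moderate", "high"].index(ib) > ["low", "moderate", "high"].index(ia)
    )
    assert sum([same or diff, switch, up]) <= 1


# --- discontinuation -------------------------------------------------------

def test_permanent_discontinuation_date_arithmetic(config):
    exposure = scripts(("simvastatin", 20), start=D(2019, 5, 1))
    # coverage ends 2019-05-31; gap to 2020-03-31 = 305 days > 180
    permanent, prior = detect_discontinuation(exposure, config)
    assert permanent and not prior


def test_gap_of_exactly_180_days_is_not_discontinuation(config):
    last = config.study_end - dt.timedelta(days=config.gap_days + 30)
    exposure = scripts(("simvastatin", 20), start=last)
    assert detect_discontinuation(exposure, config) == (False, False)


def test_interior_gap_with_resumption_is_prior_not_permanent(config):
    imap = _imap()
    dates = [D(2018, 1, 1), D(2018, 2, 1), D(2018, 9, 20), D(2020, 2, 1)]
    # gap between 2018-03-03 (coverage end) and 2018-09-20 = 201 days
    scripts_ = [
        StatinScript(d, "simvastatin", 20.0, "moderate", 30) for d in dates
    ]
    permanent, prior = detect_discontinuation(StatinExposure("T", scripts_), config)
    assert prior and not permanent


# --- intermittent dosing ---------------------------------------------------

def test_monthly_refills_are_not_intermittent(config):
    exposure = scripts(*[("simvastatin", 20)] * 12, start=D(2019, 4, 1), step=30)
    assert not detect_intermittent(exposure, config)


def test_sparse_refills_are_intermittent(config):
    # 4 scripts of 30 days over a 330-day span: MPR = 120/360 = 1/3
    exposure = scripts(*[("simvastatin", 20)] * 4, start=D(2019, 5, 1), step=110)
    assert detect_intermittent(exposure, config)


def test_mpr_exactly_at_threshold_is_not_intermittent(config):
    # 3 scripts spaced 75 days: MPR = 90 / (150 + 30) = 0.5, strict <
    exposure = scripts(*[("simvastatin", 20)] * 3, start=D(2019, 8, 1), step=75)
    assert not detect_intermittent(exposure, config)


def test_fewer_than_three_scripts_never_intermittent(config):
    exposure = scripts(("simvastatin", 20), ("simvastatin", 20), step=170)
    assert not detect_intermittent(exposure, config)


# --- low dose / SAMS -------------------------------------------------------

def test_exclusive_low_dose_detection():
    assert detect_low_dose(scripts(("simvastatin", 10), ("simvastatin", 10)), _imap())
    assert not detect_low_dose(scripts(("simvastatin", 10), ("simvastatin", 40)), _imap())


def test_low_dose_requires_non_empty_exposure():
    with pytest.raises(ValueError):
        detect_low_dose(StatinExposure("T", []), _imap())


def test_unknown_molecule_raises_config_error():
    exposure = StatinExposure(
        "T", [StatinScript(D(2019, 1, 1), "mystery", 10.0, "low", 30)]
    )
    with pytest.raises(KeyError, match="mystery"):
        detect_low_dose(exposure, _imap())


def test_sams_respects_lookback_boundary(config):
    rx = make_statin_rx(D(2019, 10, 1))
    rec_in = make_patient(rx=[rx], dx=[DiagnosisEvent(D(2018, 6, 1), "M79.1")])
    entry = entry_for(rec_in, config)
    assert detect_sams(rec_in, entry, config)
    rec_out = make_patient(
        rx=[rx],
        dx=[DiagnosisEvent(entry.lookback_start - dt.timedelta(days=1), "M79.1")],
    )
    assert not detect_sams(rec_out, entry, config)
    rec_none = make_patient(rx=[rx], dx=[DiagnosisEvent(D(2018, 6, 1), "E78.0")])
    assert not detect_sams(rec_none, entry, config)
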