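"""The generator must realise its assigned labels exactly and reproducibly."""

import datetime as dt
from pathlib import Path

import pandas as pd
import pytest
from scipy import stats

from d2care import (
    CohortConfig,
    Disposition,
    StudyWindow,
    is_well_patient,
    simulate_cohort,
    write_cohort,
)
from d2care.synthetic import default_disposition_probs


def _only_disposition(value: str) -> dict:
    return {k: (1.0 if k == value else 0.0) for k in default_disposition_probs()}


def test_degenerate_box_d_has_no_ooc_events(window):
    cfg = CohortConfig(n_patients=10, seed=1, window=window,
                       box_probs=(0.0, 0.0, 0.0, 1.0))
    cohort = simulate_cohort(cfg)
    ice, oce = pd.Timestamp(window.in_care_end), pd.Timestamp(window.ooc_end)
    ooc_visits = cohort.visits.loc[
        cohort.visits["visit_date"].ge(ice) & cohort.visits["visit_date"].lt(oce)
    ]
    ooc_vls = cohort.labs.loc[
        cohort.labs["kind"].eq("VL")
        & cohort.labs["test_date"].ge(ice)
        & cohort.labs["test_date"].lt(oce)
    ]
    assert len(ooc_visits) == 0 and len(ooc_vls) == 0
    assert (cohort.ground_truth["true_box"] == "D").all()


def test_all_well_patients_satisfy_the_well_rule(window):
    cfg = CohortConfig(
        n_patients=50, seed=2, window=window,
        disposition_probs=_only_disposition(Disposition.WELL_PATIENT.value),
    )
    cohort = simulate_cohort(cfg)
    assert (cohort.labs.loc[cohort.labs["kind"].eq("VL"), "value"] <= 20).all()
    for pid, grp in cohort.labs.loc[cohort.labs["kind"].eq("VL")].groupby("patient_id"):
        events = [(d.date(), v) for d, v in zip(grp["test_date"], grp["value"])]
        assert is_well_patient(events, window), pid


def test_upcoming_visit_patients_have_qualifying_appointment(window):
    cfg = CohortConfig(
        n_patients=40, seed=3, window=window,
        disposition_probs=_only_disposition(Disposition.UPCOMING_VISIT.value),
    )
    cohort = simulate_cohort(cfg)
    appts = cohort.appointments
    assert set(appts["patient_id"]) == set(cohort.patients["patient_id"])
    drd = pd.Timestamp(window.data_request_date)
    horizon = pd.Timestamp(window.upcoming_visit_horizon)
    assert appts["scheduled_date"].ge(drd).all()
    assert appts["scheduled_date"].lt(horizon).all()
    assert appts["kept"].isin(["kept", "missed"]).all()


def test_every_patient_is_in_care_by_construction(small_cohort, window):
    ics, ice = pd.Timestamp(window.in_care_start), pd.Timestamp(window.in_care_end)
    visits_ic = small_cohort.visits.loc[
        small_cohort.visits["visit_date"].ge(ics)
        & small_cohort.visits["visit_date"].lt(ice)
    ]
    vls_ic = small_cohort.labs.loc[
        small_cohort.labs["kind"].eq("VL")
        & small_cohort.labs["test_date"].ge(ics)
        & small_cohort.labs["test_date"].lt(ice)
    ]
    everyone = set(small_cohort.patients["patient_id"])
    assert set(visits_ic["patient_id"]) == everyone
    assert set(vls_ic["patient_id"]) == everyone


def test_same_seed_gives_byte_identical_files(tmp_path, window):
    cfg = CohortConfig(n_patients=120, seed=42, window=window)
    p1 = write_cohort(simulate_cohort(cfg), tmp_path / "a")
    p2 = write_cohort(simulate_cohort(cfg), tmp_path / "b")
    for name in p1:
        assert Path(p1[name]).read_bytes() == Path(p2[name]).read_bytes(), name


def test_default_box_counts_within_binomial_bounds(window):
    """At the study margins, box counts land inside exact 99% binomial bands."""
    n = 2958
    cohort = simulate_cohort(CohortConfig(n_patients=n, seed=12345, window=window))
    counts = cohort.ground_truth["true_box"].value_counts()
    for box, expected in [("B", 763), ("C", 1342), ("D", 853)]:
        p = expected / n
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= counts[box] <= hi, (box, counts[box], (lo, hi))
    assert counts.get("A", 0) == 0


def test_too_short_in_care_window_rejected():
    w = StudyWindow(
        in_care_start=dt.date(2017, 1, 1),
        in_care_end=dt.date(2017, 6, 1),   # 5 months: no room for the VL pair
        ooc_end=dt.date(2017, 12, 1),
        data_request_date=dt.date(2018, 1, 1),
    )
    with pytest.raises(ValueError, match="6 months apart"):
        CohortConfig(n_patients=5, seed=0, window=w)


def test_invalid_probability_vector_rejected(window):
    with pytest.raises(ValueError, match="sum to 1"):
        CohortConfig(n_patients=5, seed=0, window=window,
                     box_probs=(0.5, 0.5, 0.5, 0.5))


def test_config_roundtrips_through_yaml(tmp_path, window):
    cfg = CohortConfig(n_patients=77, seed=9, window=window, n_clinics=5)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = CohortConfig.from_yaml(tmp_path / "cfg.yaml")
    assert back == cfg
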