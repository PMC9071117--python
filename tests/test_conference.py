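"""Stepwise disposition engine: rule content, precedence, watchlist."""

import datetime as dt

import pandas as pd
import pytest

from d2care import (
    Disposition,
    is_well_patient,
    resolve_watchlist,
    run_case_conference,
)
from d2care.types import STATUS_FLAGS


@pytest.mark.parametrize(
    "vls, expected",
    [
        # two undetectable, 200 days apart (> 6 calendar months)
        ([("2017-02-01", 15), ("2017-08-20", 18)], True),
        # two undetectable but only ~3 months apart
        ([("2017-02-01", 15), ("2017-05-02", 18)], False),
        # a detectable VL between them breaks both clauses
        ([("2017-02-01", 15), ("2017-05-12", 500), ("2017-11-28", 15)], False),
        # detectable anywhere in the period fails, even after a good pair
        ([("2017-01-10", 5), ("2017-08-10", 5), ("2018-03-01", 900)], False),
        # exactly 6 calendar months apart qualifies
        ([("2017-02-01", 20), ("2017-08-01", 20)], True),
        # a VL outside the in-care/OOC period is ignored
        ([("2016-06-01", 10), ("2017-02-01", 15), ("2017-08-20", 18)], True),
        ([], False),
        ([("2017-02-01", 15)], False),
    ],
)
def test_is_well_patient_rule(window, vls, expected):
    events = [(dt.date.fromisoformat(d), v) for d, v in vls]
    assert is_well_patient(events, window) is expected


def test_day_gap_switch(window):
    events = [(dt.date(2017, 2, 1), 15), (dt.date(2017, 8, 1), 15)]  # 181 days
    assert is_well_patient(events, window)                   # 6 calendar months
    assert not is_well_patient(events, window, min_gap_days=182)


def _frame(**cols):
    return pd.DataFrame(cols)


def _conference(window, *, boxes, patients=None, visits=None, labs=None,
                appointments=None, annotations=None):
    empty_v = _frame(patient_id=[], clinic_id=[], visit_date=[])
    empty_l = _frame(patient_id=[], test_date=[], kind=[], value=[])
    empty_a = _frame(patient_id=[], clinic_id=[], scheduled_date=[], kept=[])
    if patients is None:
        patients = pd.DataFrame({"patient_id": boxes["patient_id"]})
        for f in STATUS_FLAGS:
            patients[f] = False
    return run_case_conference(
        boxes, patients,
        empty_v if visits is None else visits,
        empty_l if labs is None else labs,
        empty_a if appointments is None else appointments,
        window, annotations=annotations,
    )


def _boxes(pids, box="D"):
    return pd.DataFrame({"patient_id": pids, "in_care": True, "box": box})


def test_visit_in_lag_period_is_recent_visit(window):
    visits = _frame(patient_id=["P1"], clinic_id=["C1"],
                    visit_date=[pd.Timestamp("2018-07-11")])  # 10 d after ooc_end
    out = _conference(window, boxes=_boxes(["P1"]), visits=visits)
    assert out.loc[0, "disposition"] == Disposition.RECENT_VISIT.value
    assert not out.loc[0, "watchlist_flag"]


def test_deceased_flag_fires_when_nothing_earlier_does(window):
    patients = pd.DataFrame({"patient_id": ["P1"]})
    for f in STATUS_FLAGS:
        patients[f] = f == "deceased"
    out = _conference(window, boxes=_boxes(["P1"]), patients=patients)
    assert out.loc[0, "disposition"] == Disposition.DECEASED.value


def test_well_patient_outranks_deceased_flag(window):
    """Order-faithfulness: rule 1 beats rule 8 even when both fire."""
    patients = pd.DataFrame({"patient_id": ["P1"]})
    for f in STATUS_FLAGS:
        patients[f] = f == "deceased"
    labs = _frame(
        patient_id=["P1", "P1"],
        test_date=[pd.Timestamp("2017-02-01"), pd.Timestamp("2017-09-01")],
        kind=["VL", "VL"], value=[10.0, 10.0],
    )
    out = _conference(window, boxes=_boxes(["P1"], box="C"),
                      patients=patients, labs=labs)
    assert out.loc[0, "disposition"] == Disposition.WELL_PATIENT.value


def test_recent_visit_outranks_upcoming_appointment(window):
    visits = _frame(patient_id=["P1"], clinic_id=["C1"],
                    visit_date=[pd.Timestamp("2018-07-05")])
    appts = _frame(patient_id=["P1"], clinic_id=["C1"],
                   scheduled_date=[pd.Timestamp("2018-08-15")], kept=["unknown"])
    out = _conference(window, boxes=_boxes(["P1"]), visits=visits,
                      appointments=appts)
    assert out.loc[0, "disposition"] == Disposition.RECENT_VISIT.value


def test_appointment_within_three_months_is_upcoming_and_watchlisted(window):
    appts = _frame(patient_id=["P1", "P2"], clinic_id=["C1", "C1"],
                   scheduled_date=[pd.Timestamp("2018-08-15"),
                                   pd.Timestamp("2018-11-15")],  # beyond horizon
                   kept=["unknown", "unknown"])
    out = _conference(window, boxes=_boxes(["P1", "P2"]), appointments=appts)
    out = out.set_index("patient_id")
    assert out.loc["P1", "disposition"] == Disposition.UPCOMING_VISIT.value
    assert bool(out.loc["P1", "watchlist_flag"])
    assert out.loc["P2", "disposition"] == Disposition.RANDOMIZABLE.value


def test_annotation_drives_flag_disposition(window):
    ann = pd.DataFrame({"patient_id": ["P1"],
                        "disposition_code": ["MOVED_OUT_OF_STATE"],
                        "note": ["clinic review"]})
    out = _conference(window, boxes=_boxes(["P1"]), annotations=ann)
    assert out.loc[0, "disposition"] == Disposition.MOVED_OUT_OF_STATE.value


def test_unknown_annotation_code_rejected(window):
    ann = pd.DataFrame({"patient_id": ["P1"], "disposition_code": ["ABDUCTED"],
                        "note": [""]})
    with pytest.raises(ValueError, match="ABDUCTED"):
        _conference(window, boxes=_boxes(["P1"]), annotations=ann)


def test_box_a_patients_are_not_conferenced(window):
    boxes = pd.DataFrame({"patient_id": ["P1", "P2"], "in_care": True,
                          "box": ["A", "D"]})
    out = _conference(window, boxes=boxes)
    assert out["patient_id"].tolist() == ["P2"]


def test_watchlist_resolution_conserves_and_splits(window):
    conf = pd.DataFrame({
        "patient_id": ["P1", "P2", "P3", "P4"],
        "box": ["B", "C", "D", "D"],
        "disposition": [Disposition.UPCOMING_VISIT.value] * 3
        + [Disposition.RANDOMIZABLE.value],
        "watchlist_flag": [True, True, True, False],
    })
    appts = _frame(
        patient_id=["P1", "P2", "P3"], clinic_id=["C1"] * 3,
        scheduled_date=[pd.Timestamp("2018-08-15")] * 3,
        kept=["missed", "kept", "unknown"],
    )
    res = resolve_watchlist(conf, appts)
    assert res.additions["patient_id"].tolist() == ["P1"]
    assert res.kept["patient_id"].tolist() == ["P2"]
    assert res.pending["patient_id"].tolist() == ["P3"]
    assert sum(res.counts.values()) == 3


def test_empty_watchlist_yields_no_additions(window):
    conf = pd.DataFrame({"patient_id": ["P1"], "box": ["D"],
                         "disposition": [Disposition.RANDOMIZABLE.value],
                         "watchlist_flag": [False]})
    res = resolve_watchlist(conf, _frame(patient_id=[], clinic_id=[],
                                         scheduled_date=[], kept=[]))
    assert len(res.additions) == 0 and len(res.kept) == 0 and len(res.pending) == 0


def test_all_kept_watchlist_adds_nobody(window):
    conf = pd.DataFrame({"patient_id": ["P1", "P2"], "box": ["B", "C"],
                         "disposition": [Disposition.UPCOMING_VISIT.value] * 2,
                         "watchlist_flag": [True, True]})
    appts = _frame(patient_id=["P1", "P2"], clinic_id=["C1", "C1"],
                   scheduled_date=[pd.Timestamp("2018-08-15")] * 2,
                   kept=["kept", "kept"])
    res = resolve_watchlist(conf, appts)
    assert len(res.additions) == 0
    assert len(res.kept) == 2


def test_disposition_recovery_on_simulated_cohort(small_cohort, window):
    from d2care import classify_cohort

    boxes = classify_cohort(small_cohort.patients, small_cohort.visits,
                            small_cohort.labs, window)
    out = run_case_conference(
        boxes, small_cohort.patients, small_cohort.visits, small_cohort.labs,
        small_cohort.appointments, window, annotations=small_cohort.annotations,
    )
    merged = out.merge(small_cohort.ground_truth, on="patient_id")
    assert (merged["disposition"] == merged["true_disposition"]).all()
    assert len(out) == (small_cohort.ground_truth["true_box"] != "A").sum()
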