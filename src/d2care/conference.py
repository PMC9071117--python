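"""Case-conference disposition engine and upcoming-visit watchlist.

Every potentially-OOC patient (Box B/C/D) receives exactly one disposition,
determined by a fixed stepwise rule list; evaluation stops at the first
rule that fires:

 1. WELL_PATIENT — two chronologically adjacent viral loads, both
    undetectable (≤20 copies/ml), at least 6 calendar months apart, and no
    detectable VL anywhere in the in-care + OOC period.
 2. RECENT_VISIT — a clinic visit inside the lag period
    ``[ooc_end, data_request_date)``.
 3. UPCOMING_VISIT — an appointment scheduled within 3 calendar months of
    the data request.  These patients go on a watchlist and are re-reviewed:
    a missed appointment makes them randomizable after all.
 4–10. Flag-driven dispositions (extended-care facility, incarcerated,
    moved out of state, not our patient, deceased, provider discretion,
    other), from patient status flags and/or clinic annotations.
 11. RANDOMIZABLE — nothing above fired.

A patient can satisfy several rules (e.g. well patient *and* deceased flag);
precedence decides, and such conflicts are counted in the run log.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .dates import add_months, add_months_series
from .types import (
    Disposition,
    FLAG_DISPOSITIONS,
    FLAG_FOR_DISPOSITION,
    VL_UNDETECTABLE_MAX,
)
from .window import StudyWindow

__all__ = [
    "is_well_patient",
    "run_case_conference",
    "resolve_watchlist",
    "WatchlistResolution",
]

log = logging.getLogger(__name__)


def is_well_patient(
    vl_events: Sequence[tuple[dt.date, float]],
    window: StudyWindow,
    *,
    threshold: float = VL_UNDETECTABLE_MAX,
    min_gap_days: int | None = None,
) -> bool:
    """Well-patient rule on one patient's VL history.

    True iff, among VLs dated in ``[in_care_start, ooc_end)``, (a) none is
    detectable (> *threshold*), and (b) some pair of chronologically
    adjacent VLs is at least 6 calendar months apart (or *min_gap_days*
    days when given).  With (a) holding, every VL in the window is
    undetectable, so any adjacent pair is a pair of consecutive
    undetectable results.
    """
    in_window = sorted(
        (d, v)
        for d, v in vl_events
        if window.in_care_start <= d < window.ooc_end
    )
    if any(v > threshold for _, v in in_window):
        return False
    for (d1, _), (d2, _) in zip(in_window, in_window[1:]):
        if min_gap_days is not None:
            if (d2 - d1).days >= min_gap_days:
                return True
        elif d2 >= add_months(d1, 6):
            return True
    return False


def _well_patient_ids(
    labs: pd.DataFrame, window: StudyWindow, threshold: float, min_gap_days: int | None
) -> set:
    """Vectorised well-patient rule over the whole lab table."""
    if labs.empty:
        return set()
    ics = pd.Timestamp(window.in_care_start)
    oce = pd.Timestamp(window.ooc_end)
    dates = pd.to_datetime(labs["test_date"])
    vls = labs.loc[labs["kind"].eq("VL") & dates.ge(ics) & dates.lt(oce)]
    if vls.empty:
        return set()
    detectable = set(vls.loc[vls["value"] > threshold, "patient_id"])
    und = vls.loc[~vls["patient_id"].isin(detectable)].sort_values(
        ["patient_id", "test_date"]
    )
    if und.empty:
        return set()
    same = und["patient_id"].eq(und["patient_id"].shift(-1))
    nxt = und["test_date"].shift(-1)
    if min_gap_days is not None:
        gap_ok = (nxt - und["test_date"]).dt.days >= min_gap_days
    else:
        gap_ok = nxt >= add_months_series(und["test_date"], 6)
    return set(und.loc[same & gap_ok, "patient_id"])


def run_case_conference(
    boxes: pd.DataFrame,
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    labs: pd.DataFrame,
    appointments: pd.DataFrame,
    window: StudyWindow,
    annotations: pd.DataFrame | None = None,
    *,
    vl_threshold: float = VL_UNDETECTABLE_MAX,
    well_min_gap_days: int | None = None,
) -> pd.DataFrame:
    """Assign one disposition to every potentially-OOC (Box B/C/D) patient.

    *boxes* is the output of :func:`d2care.eligibility.classify_cohort`;
    *annotations* is an optional clinic-review table with columns
    ``patient_id, disposition_code`` carrying flag dispositions (4)-(10).

    Returns ``patient_id, box, disposition, fired_rule_evidence,
    watchlist_flag`` with exactly one row per B/C/D patient.
    """
    ooc = boxes.loc[boxes["box"].isin(["B", "C", "D"]), ["patient_id", "box"]].copy()
    pid = ooc["patient_id"]

    oce = pd.Timestamp(window.ooc_end)
    drd = pd.Timestamp(window.data_request_date)
    horizon = pd.Timestamp(window.upcoming_visit_horizon)

    def _ids_between(df: pd.DataFrame, col: str, start, end) -> set:
        if df.empty:
            return set()
        dates = pd.to_datetime(df[col])
        return set(df.loc[dates.ge(start) & dates.lt(end), "patient_id"])

    well = pid.isin(_well_patient_ids(labs, window, vl_threshold, well_min_gap_days))
    recent = pid.isin(_ids_between(visits, "visit_date", oce, drd))
    upcoming = pid.isin(_ids_between(appointments, "scheduled_date", drd, horizon))

    flag_masks = _flag_masks(pid, patients, annotations)

    conditions = [well.to_numpy(), recent.to_numpy(), upcoming.to_numpy()]
    choices = [
        Disposition.WELL_PATIENT.value,
        Disposition.RECENT_VISIT.value,
        Disposition.UPCOMING_VISIT.value,
    ]
    evidence = [
        "two adjacent undetectable VLs >=6 months apart, none detectable",
        "clinic visit in lag period",
        "appointment scheduled within 3 months of data request",
    ]
    for disp in FLAG_DISPOSITIONS:
        conditions.append(flag_masks[disp].to_numpy())
        choices.append(disp.value)
        evidence.append(f"status flag/annotation: {FLAG_FOR_DISPOSITION[disp]}")

    stacked = np.column_stack(conditions)
    n_conflicts = int((stacked.sum(axis=1) > 1).sum())
    if n_conflicts:
        log.info(
            "%d patients satisfied more than one disposition rule; "
            "stepwise precedence applied", n_conflicts,
        )

    disposition = np.select(conditions, choices, default=Disposition.RANDOMIZABLE.value)
    fired = np.select(conditions, evidence, default="no rule fired")
    out = ooc.reset_index(drop=True)
    out["disposition"] = disposition
    out["fired_rule_evidence"] = fired
    out["watchlist_flag"] = out["disposition"].eq(Disposition.UPCOMING_VISIT.value)
    return out


def _flag_masks(
    pid: pd.Series, patients: pd.DataFrame, annotations: pd.DataFrame | None
) -> dict[Disposition, pd.Series]:
    """Boolean mask per flag disposition, merging status flags and annotations."""
    masks = {}
    ann_ids: dict[str, set] = {}
    if annotations is not None and len(annotations):
        for code, grp in annotations.groupby("disposition_code"):
            ann_ids[str(code)] = set(grp["patient_id"])
        known = {d.value for d in FLAG_DISPOSITIONS}
        unknown = set(ann_ids) - known
        if unknown:
            raise ValueError(
                f"annotations carry unknown disposition codes: {sorted(unknown)}; "
                f"allowed: {sorted(known)}"
            )
    flagged = patients.set_index("patient_id")
    for disp in FLAG_DISPOSITIONS:
        col = FLAG_FOR_DISPOSITION[disp]
        if col in flagged.columns:
            from_flags = pid.map(flagged[col].astype(bool)).fillna(False)
        else:
            from_flags = pd.Series(False, index=pid.index)
        from_ann = pid.isin(ann_ids.get(disp.value, set()))
        masks[disp] = (from_flags | from_ann).astype(bool)
    return masks


class WatchlistResolution:
    """Outcome of re-reviewing the upcoming-visit watchlist."""

    def __init__(self, additions: pd.DataFrame, kept: pd.DataFrame,
                 pending: pd.DataFrame):
        self.additions = additions  # missed their appointment -> randomizable
        self.kept = kept            # kept it -> remain non-randomized
        self.pending = pending      # appointment status still unknown

    @property
    def counts(self) -> dict[str, int]:
        return {
            "watchlist_missed": len(self.additions),
            "watchlist_kept": len(self.kept),
            "watchlist_pending": len(self.pending),
        }


def resolve_watchlist(
    conference: pd.DataFrame, appointments: pd.DataFrame
) -> WatchlistResolution:
    """Split the watchlist by appointment outcome.

    Patients whose qualifying appointment was missed become randomizable;
    kept stays UPCOMING_VISIT (non-randomized); ``kept == unknown`` is held
    as pending.  Conservation: missed + kept + pending = watchlist size.
    """
    watch = conference.loc[conference["watchlist_flag"], ["patient_id", "box"]]
    # one status per patient: 'missed' wins over 'kept' (any missed visit
    # makes the patient reachable for randomization), 'unknown' only if
    # nothing else is recorded
    rank = {"missed": 0, "kept": 1, "unknown": 2}
    appt = appointments.loc[appointments["patient_id"].isin(watch["patient_id"])].copy()
    if len(appt):
        appt["rank"] = appt["kept"].map(rank)
        if appt["rank"].isna().any():
            bad = sorted(appt.loc[appt["rank"].isna(), "kept"].unique())
            raise ValueError(f"appointment 'kept' must be kept/missed/unknown, got {bad}")
        status = appt.sort_values("rank").groupby("patient_id")["kept"].first()
    else:
        status = pd.Series(dtype=object)
    merged = watch.assign(status=watch["patient_id"].map(status).fillna("unknown"))
    return WatchlistResolution(
        additions=merged.loc[merged["status"].eq("missed"), ["patient_id", "box"]]
        .reset_index(drop=True),
        kept=merged.loc[merged["status"].eq("kept"), ["patient_id", "box"]]
        .reset_index(drop=True),
        pending=merged.loc[merged["status"].eq("unknown"), ["patient_id", "box"]]
        .reset_index(drop=True),
    )
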