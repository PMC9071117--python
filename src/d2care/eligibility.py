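"""In-care determination, Box A/B/C/D classification, last in-care labs.

A patient is *in care* iff the in-care year ``[in_care_start, in_care_end)``
contains at least one clinic visit AND at least one viral load.  In-care
patients are then classified by what the OOC window
``[in_care_end, ooc_end)`` contains:

    visit & VL        -> Box A  (still in care; excluded)
    VL only           -> Box B
    visit only        -> Box C
    neither           -> Box D

Only VL labs drive the box class; a patient with a CD4 but no VL in the OOC
window counts as lacking labs for box purposes (the operational definition
used by the enrollment flow), and the discrepancy is recorded in the run
log because the looser eligibility phrasing ("no CD4/Viral Load") would
have read it the other way.

All boundaries are half-open: an event dated exactly on ``in_care_end``
belongs to the OOC window, not the in-care year.
"""

from __future__ import annotations

import datetime as dt
import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .rounding import round_half_up
from .types import Box, CD4_BINS, VL_UNDETECTABLE_MAX
from .window import StudyWindow

__all__ = [
    "is_in_care",
    "classify_box",
    "classify_cohort",
    "bin_cd4",
    "bin_vl",
    "last_in_care_labs",
    "last_in_care_labs_cohort",
    "box_shares",
]

log = logging.getLogger(__name__)


def _in(dates: Iterable[dt.date], start: dt.date, end: dt.date) -> bool:
    return any(start <= d < end for d in dates)


def is_in_care(
    visit_dates: Iterable[dt.date],
    vl_dates: Iterable[dt.date],
    window: StudyWindow,
) -> bool:
    """≥1 clinic visit AND ≥1 VL inside the in-care year (both required)."""
    return _in(visit_dates, window.in_care_start, window.in_care_end) and _in(
        vl_dates, window.in_care_start, window.in_care_end
    )


def classify_box(
    visit_dates: Iterable[dt.date],
    vl_dates: Iterable[dt.date],
    window: StudyWindow,
) -> Box:
    """Box from visit/VL presence in the OOC window (caller ensures in-care)."""
    has_visit = _in(visit_dates, window.in_care_end, window.ooc_end)
    has_vl = _in(vl_dates, window.in_care_end, window.ooc_end)
    if has_visit and has_vl:
        return Box.A
    if has_vl:
        return Box.B
    if has_visit:
        return Box.C
    return Box.D


def classify_cohort(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    labs: pd.DataFrame,
    window: StudyWindow,
) -> pd.DataFrame:
    """Vectorised in-care + box classification for a whole cohort.

    Returns a DataFrame with one row per patient in *patients*:
    ``patient_id, in_care, box`` — ``box`` is NA for patients who do not
    meet the in-care definition (they are not eligible for the cycle).
    """
    ics = pd.Timestamp(window.in_care_start)
    ice = pd.Timestamp(window.in_care_end)
    oce = pd.Timestamp(window.ooc_end)

    vls = labs.loc[labs["kind"].eq("VL")]
    cd4s = labs.loc[labs["kind"].eq("CD4")]

    def _ids(df: pd.DataFrame, col: str, start: pd.Timestamp, end: pd.Timestamp) -> set:
        if df.empty:
            return set()
        dates = pd.to_datetime(df[col])
        return set(df.loc[dates.ge(start) & dates.lt(end), "patient_id"])

    visit_ic = _ids(visits, "visit_date", ics, ice)
    vl_ic = _ids(vls, "test_date", ics, ice)
    visit_ooc = _ids(visits, "visit_date", ice, oce)
    vl_ooc = _ids(vls, "test_date", ice, oce)
    cd4_ooc = _ids(cd4s, "test_date", ice, oce)

    pid = patients["patient_id"]
    in_care = pid.isin(visit_ic) & pid.isin(vl_ic)
    has_visit = pid.isin(visit_ooc).to_numpy()
    has_vl = pid.isin(vl_ooc).to_numpy()
    box = np.select(
        [has_visit & has_vl, ~has_visit & has_vl, has_visit & ~has_vl],
        [Box.A.value, Box.B.value, Box.C.value],
        default=Box.D.value,
    )
    box = pd.Series(box, index=patients.index).where(in_care, pd.NA)

    n_cd4_only = int((pid.isin(cd4_ooc) & ~pid.isin(vl_ooc) & in_care).sum())
    if n_cd4_only:
        log.info(
            "%d in-care patients have a CD4 but no VL in the OOC window; "
            "treated as lacking OOC labs for box classification (VL-only rule)",
            n_cd4_only,
        )
    return pd.DataFrame(
        {"patient_id": pid, "in_care": in_care, "box": box}
    ).reset_index(drop=True)


def bin_cd4(value: float) -> str:
    """CD4 (cells/µl) into the reporting bins <200 / 200-299 / 300-499 / >=500."""
    if value < 200:
        return CD4_BINS[0]
    if value < 300:
        return CD4_BINS[1]
    if value < 500:
        return CD4_BINS[2]
    return CD4_BINS[3]


def bin_vl(value: float, threshold: float = VL_UNDETECTABLE_MAX) -> str:
    """VL (copies/ml) into undetectable (≤ threshold) vs detectable."""
    return "undetectable" if value <= threshold else "detectable"


def last_in_care_labs(
    labs: pd.DataFrame, window: StudyWindow
) -> tuple[str | None, str | None]:
    """Bins of the latest in-care CD4 and latest in-care VL for one patient.

    Returns ``(cd4_bin, vl_bin)``; an element is None when no lab of that
    kind falls in the in-care year (the published denominators differ by
    lab kind for exactly this reason).
    """
    ics, ice = pd.Timestamp(window.in_care_start), pd.Timestamp(window.in_care_end)
    win = labs.loc[labs["test_date"].ge(ics) & labs["test_date"].lt(ice)]
    out: list[str | None] = []
    for kind, binner in (("CD4", bin_cd4), ("VL", bin_vl)):
        sub = win.loc[win["kind"].eq(kind)]
        if sub.empty:
            out.append(None)
        else:
            out.append(binner(float(sub.loc[sub["test_date"].idxmax(), "value"])))
    return out[0], out[1]


def last_in_care_labs_cohort(
    patients: pd.DataFrame, labs: pd.DataFrame, window: StudyWindow
) -> pd.DataFrame:
    """Vectorised :func:`last_in_care_labs`: one row per patient with
    ``patient_id, last_cd4_bin, last_vl_bin`` (NA when missing)."""
    ics, ice = pd.Timestamp(window.in_care_start), pd.Timestamp(window.in_care_end)
    win = labs.loc[labs["test_date"].ge(ics) & labs["test_date"].lt(ice)]
    out = patients[["patient_id"]].copy()
    for kind, col, binner in (
        ("CD4", "last_cd4_bin", bin_cd4),
        ("VL", "last_vl_bin", bin_vl),
    ):
        sub = win.loc[win["kind"].eq(kind)].sort_values("test_date")
        last = sub.groupby("patient_id")["value"].last()
        out[col] = out["patient_id"].map(last.map(binner))
    return out


def box_shares(boxes: pd.Series, decimals: int = 1) -> dict[str, float]:
    """Percent share of each box among potentially-OOC (B/C/D) patients."""
    ooc = boxes[boxes.isin(["B", "C", "D"])]
    n = len(ooc)
    return {
        b: round_half_up(100.0 * (ooc == b).sum() / n, decimals) if n else 0.0
        for b in ("B", "C", "D")
    }
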