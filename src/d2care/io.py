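"""Flat-file exchange: clinic and surveillance CSV extracts.

The exchange format is deliberately plain so round-trips are bit-exact:
comma-separated, UTF-8, header row required, ISO 8601 dates.  Reading is
strict — a missing column is fatal, a row with an unparseable date is
rejected *visibly* (returned with its row number, never silently dropped),
and duplicate visit rows are deduplicated with a logged count.

Files:
    clinic_visits.csv      patient_id, clinic_id, visit_date
    appointments.csv       patient_id, clinic_id, scheduled_date, kept
    surveillance_labs.csv  patient_id, test_date, kind, value
    patients.csv           demographics + status flags (0/1 columns)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .types import (
    APPOINTMENT_COLUMNS,
    LAB_COLUMNS,
    PATIENT_COLUMNS,
    STATUS_FLAGS,
    VISIT_COLUMNS,
)

__all__ = [
    "ExtractError",
    "ClinicExtract",
    "read_clinic_extract",
    "read_surveillance_extract",
    "read_patients",
    "write_visits",
    "write_appointments",
    "write_labs",
    "write_patients",
    "join_surveillance",
]

log = logging.getLogger(__name__)

_DATE_FORMAT = "%Y-%m-%d"


class ExtractError(ValueError):
    """A structural problem with an extract file (e.g. missing column)."""


def _read(path: str | Path, required: list[str], date_cols: list[str]):
    """Strictly read a CSV; return (valid_df, rejected_df).

    rejected_df carries the offending rows plus ``row_number`` (1-based,
    excluding the header) and ``reason``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"extract file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ExtractError(f"{path}: missing required column(s) {missing}")
    df = df[required].copy()
    bad = pd.Series(False, index=df.index)
    for col in date_cols:
        parsed = pd.to_datetime(df[col], format=_DATE_FORMAT, errors="coerce")
        bad |= parsed.isna()
        df[col] = parsed
    rejected = df.loc[bad].copy()
    rejected.insert(0, "row_number", rejected.index + 1)
    rejected["reason"] = "unparseable date"
    if len(rejected):
        log.warning(
            "%s: rejected %d row(s) with unparseable dates (rows %s)",
            path, len(rejected), rejected["row_number"].tolist(),
        )
    return df.loc[~bad].reset_index(drop=True), rejected.reset_index(drop=True)


@dataclass
class ClinicExtract:
    """One clinic submission: visits, scheduled appointments, and an error
    report (rejected rows + duplicate count) that callers must surface."""

    visits: pd.DataFrame
    appointments: pd.DataFrame
    rejected: pd.DataFrame
    n_duplicate_visits: int = 0


def read_clinic_extract(
    visits_path: str | Path, appointments_path: str | Path | None = None
) -> ClinicExtract:
    """Read the clinic visit list and (optionally) the appointment list."""
    visits, rej_v = _read(visits_path, VISIT_COLUMNS, ["visit_date"])
    n_dup = int(visits.duplicated(subset=["patient_id", "visit_date"]).sum())
    if n_dup:
        log.warning("%s: deduplicated %d duplicate visit row(s)", visits_path, n_dup)
        visits = visits.drop_duplicates(
            subset=["patient_id", "visit_date"], keep="first"
        ).reset_index(drop=True)
    if appointments_path is not None:
        appts, rej_a = _read(
            appointments_path, APPOINTMENT_COLUMNS, ["scheduled_date"]
        )
        bad_kept = ~appts["kept"].isin(["kept", "missed", "unknown"])
        if bad_kept.any():
            raise ExtractError(
                f"{appointments_path}: invalid 'kept' values "
                f"{sorted(appts.loc[bad_kept, 'kept'].unique())}"
            )
    else:
        appts = pd.DataFrame(columns=APPOINTMENT_COLUMNS)
        rej_a = pd.DataFrame()
    rejected = pd.concat([rej_v, rej_a], ignore_index=True)
    return ClinicExtract(
        visits=visits, appointments=appts, rejected=rejected,
        n_duplicate_visits=n_dup,
    )


def read_surveillance_extract(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the surveillance lab extract; returns (labs, rejected_rows)."""
    labs, rejected = _read(path, LAB_COLUMNS, ["test_date"])
    labs["value"] = pd.to_numeric(labs["value"], errors="coerce")
    bad = labs["value"].isna() | (labs["value"] < 0)
    if bad.any():
        extra = labs.loc[bad].copy()
        extra.insert(0, "row_number", extra.index + 1)
        extra["reason"] = "invalid lab value"
        rejected = pd.concat([rejected, extra], ignore_index=True)
        labs = labs.loc[~bad].reset_index(drop=True)
    bad_kind = ~labs["kind"].isin(["VL", "CD4"])
    if bad_kind.any():
        raise ExtractError(
            f"{path}: unknown lab kind(s) {sorted(labs.loc[bad_kind, 'kind'].unique())}"
        )
    return labs, rejected


def read_patients(path: str | Path) -> pd.DataFrame:
    """Read demographics + status flags; flags come back as booleans."""
    df, rejected = _read(path, PATIENT_COLUMNS, ["birth_date"])
    if len(rejected):
        raise ExtractError(
            f"{path}: {len(rejected)} patient row(s) with unparseable birth_date "
            f"(rows {rejected['row_number'].tolist()})"
        )
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ExtractError(f"{path}: duplicate patient_id {dup}")
    for flag in STATUS_FLAGS:
        df[flag] = df[flag].astype(int).astype(bool)
    return df


def _write(df: pd.DataFrame, path: str | Path, date_cols: list[str]) -> None:
    out = df.copy()
    for col in date_cols:
        out[col] = pd.to_datetime(out[col]).dt.strftime(_DATE_FORMAT)
    out.to_csv(path, index=False)


def write_visits(df: pd.DataFrame, path: str | Path) -> None:
    _write(df[VISIT_COLUMNS], path, ["visit_date"])


def write_appointments(df: pd.DataFrame, path: str | Path) -> None:
    _write(df[APPOINTMENT_COLUMNS], path, ["scheduled_date"])


def write_labs(df: pd.DataFrame, path: str | Path) -> None:
    _write(df[LAB_COLUMNS], path, ["test_date"])


def write_patients(df: pd.DataFrame, path: str | Path) -> None:
    out = df[PATIENT_COLUMNS].copy()
    for flag in STATUS_FLAGS:
        out[flag] = out[flag].astype(int)
    _write(out, path, ["birth_date"])


def join_surveillance(
    visits: pd.DataFrame,
    labs: pd.DataFrame,
    patients: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconcile clinic visits with surveillance labs into one row per patient.

    Returns ``(joined, exceptions)``.  *joined* has one row per patient in
    *patients* with tuple-valued columns ``visit_dates, vl_dates, vl_values,
    cd4_dates, cd4_values`` and a ``surveillance_only`` flag (labs present
    but no clinic visit on file).  Events whose patient_id is unknown go to
    *exceptions* (with a ``source`` column) — an orphan never aborts a run.
    The join is lossless: every input event lands in exactly one of the two
    outputs.
    """
    known = set(patients["patient_id"])
    orphan_v = visits.loc[~visits["patient_id"].isin(known)].copy()
    orphan_l = labs.loc[~labs["patient_id"].isin(known)].copy()
    orphan_v["source"] = "clinic_visits"
    orphan_l["source"] = "surveillance_labs"
    exceptions = pd.concat([orphan_v, orphan_l], ignore_index=True)
    if len(exceptions):
        log.warning("join: %d orphan event(s) routed to exceptions", len(exceptions))

    ok_visits = visits.loc[visits["patient_id"].isin(known)]
    ok_labs = labs.loc[labs["patient_id"].isin(known)]

    def _agg(df, date_col, value_col=None):
        df = df.sort_values([date_col])
        dates = df.groupby("patient_id")[date_col].agg(tuple)
        if value_col is None:
            return dates, None
        return dates, df.groupby("patient_id")[value_col].agg(tuple)

    v_dates, _ = _agg(ok_visits, "visit_date")
    vls = ok_labs.loc[ok_labs["kind"].eq("VL")]
    cd4s = ok_labs.loc[ok_labs["kind"].eq("CD4")]
    vl_dates, vl_values = _agg(vls, "test_date", "value")
    cd4_dates, cd4_values = _agg(cd4s, "test_date", "value")

    joined = patients[["patient_id", "clinic_id"]].copy()
    empty = ()
    for name, series in (
        ("visit_dates", v_dates),
        ("vl_dates", vl_dates),
        ("vl_values", vl_values),
        ("cd4_dates", cd4_dates),
        ("cd4_values", cd4_values),
    ):
        joined[name] = joined["patient_id"].map(series)
        joined[name] = joined[name].apply(lambda x: x if isinstance(x, tuple) else empty)
    joined["surveillance_only"] = (
        joined["visit_dates"].apply(len).eq(0)
        & (joined["vl_dates"].apply(len) + joined["cd4_dates"].apply(len)).gt(0)
    )
    return joined, exceptions
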